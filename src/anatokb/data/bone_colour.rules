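# Demonstration rule crossing the anatomy and 3D domains: bones are
# conventionally rendered yellow.
R12: IF (?x rdf:type mcf:3D-object) AND (?x mcf:Describes ?y) AND (?y rdfs:subClassOf mcf:Bone) THEN (?x mcf:hasColour "yellow")
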