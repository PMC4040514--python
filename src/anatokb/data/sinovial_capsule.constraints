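# Anatomical well-formedness: every sinovial joint has an articular capsule.
C1: IF (?j rdf:type mcf:Sinovial_joint) REQUIRE (?c rdf:type mcf:Articular_capsule) AND (?c mcf:PartOf ?j)
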