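# Core anatomy rule set: 11 safe rules.
# Transitivity of the taxonomy, the partonomy, and function involvement.
R1: IF (?a rdfs:subClassOf ?c) AND (?c rdfs:subClassOf ?b) THEN (?a rdfs:subClassOf ?b)
R2: IF (?a mcf:PartOf ?c) AND (?c mcf:PartOf ?b) THEN (?a mcf:PartOf ?b)
R3: IF (?a mcf:IsInvolvedIn ?c) AND (?c mcf:IsInvolvedIn ?b) THEN (?a mcf:IsInvolvedIn ?b)
# Relation specializations: laterality links are subclass links; realizing a
# function implies contributing to it.
R4: IF (?a mcf:leftSubClassOf ?b) THEN (?a rdfs:subClassOf ?b)
R5: IF (?a mcf:rightSubClassOf ?b) THEN (?a rdfs:subClassOf ?b)
R6: IF (?a mcf:hasFunction ?b) THEN (?a mcf:contributesTo ?b)
# Cross-relation connections that hold in anatomy.
R7: IF (?a rdfs:subClassOf ?c) AND (?c mcf:InsertOn ?b) THEN (?a mcf:InsertOn ?b)
R8: IF (?a mcf:IsInvolvedIn ?c) AND (?c rdfs:subClassOf ?b) THEN (?a mcf:IsInvolvedIn ?b)
R9: IF (?a mcf:contributesTo ?c) AND (?c rdfs:subClassOf ?b) THEN (?a mcf:contributesTo ?b)
R10: IF (?a mcf:contributesTo ?c) AND (?c mcf:IsInvolvedIn ?b) THEN (?a mcf:contributesTo ?b)
R11: IF (?a mcf:InsertOn ?c) AND (?c mcf:PartOf ?b) THEN (?a mcf:InsertOn ?b)
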