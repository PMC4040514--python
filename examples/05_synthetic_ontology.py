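"""Seeded synthetic ontologies for stress-testing the reasoning machinery.

Generates a reproducible anatomy-like knowledge base (taxonomy tree,
partonomy, insertions, function forest, laterality on part of the taxonomy),
saturates it, and prints how much each rule inferred.  Same seed, same store —
byte-identical serialization.
"""

import anatokb as ak

params = ak.SynthParams(depth=4, branching=3, n_functions=15, seed=7, laterality_fraction=0.4)
store = ak.generate_synthetic_ontology(params)
again = ak.generate_synthetic_ontology(params)
assert ak.serialize_rdf(store) == ak.serialize_rdf(again)

closed = ak.saturate(store, ak.default_ruleset(), log_derivations=False)
print(f"generated {len(store)} triples (seed {params.seed}); closure has {len(closed)}")
print(f"rounds to fixpoint: {closed.report.rounds}")
for rule_id, n in sorted(closed.report.inferred_by_rule.items()):
    print(f"  {rule_id:>4} inferred {n}")
print("reproducible: two builds with the same seed serialize identically.")
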