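"""Constraint-based anatomical model checking.

The packaged constraint states that every sinovial joint has an articular
capsule as a part.  A store declaring a joint without one fails the check with
a violation naming the joint; adding the capsule makes the model valid.
"""

import anatokb as ak
from anatokb import schema as S
from anatokb.fixture import mcf
from anatokb.model import Triple, TripleStore

constraints = ak.default_constraints()
store = TripleStore([Triple(mcf("Left_knee_joint"), S.RDF_TYPE, mcf("Sinovial_joint"))])
closed = ak.saturate(store, ak.default_ruleset())

report = ak.validate_model(closed, constraints)
print(f"capsule-less joint -> {len(report)} violation(s):")
for v in report.violations:
    print("  ", v)

store.add(Triple(mcf("Capsule1"), S.RDF_TYPE, mcf("Articular_capsule")))
store.add(Triple(mcf("Capsule1"), S.PARTOF, mcf("Left_knee_joint")))
closed = ak.saturate(store, ak.default_ruleset())
print(f"after adding the capsule -> valid: {ak.validate_model(closed, constraints).ok}")
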