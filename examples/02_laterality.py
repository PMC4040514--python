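"""Generate left/right specializations of an anatomical subtree.

Starting from the knee-joint subclass subtree, laterality expansion adds
Left_X/Right_X classes linked by leftSubClassOf/rightSubClassOf and mirrors
the subtree's internal links into both copies.  The printed triples show the
new specialization edges; the counts show that each copy replicates the
original structure exactly.
"""

import anatokb as ak
from anatokb.fixture import knee_joint_subtree, mcf

subtree = knee_joint_subtree()
expanded = ak.expand_laterality(subtree, mcf("knee_joint"))

print(f"subtree triples before: {len(subtree)}, after expansion: {len(expanded)}")
print(ak.serialize_rdf(expanded, ak.TURTLE))
print("every subclass edge now exists in three versions: original, Left_, Right_.")
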