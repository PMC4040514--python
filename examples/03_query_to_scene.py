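"""From a conjunctive query to highlighted 3D scene objects.

Asks which bones the tendons of the sartorius insert on.  On the raw store the
only answer is the asserted epiphysis; after saturation the insertion has
propagated up the partonomy to the whole right tibia.  The answers then drive
the scene selection: the object describing the tibia is highlighted yellow.
"""

import anatokb as ak
from anatokb.fixture import mcf, reference_fixture, tendon_insertion_query_text
from anatokb.scene import select_objects, selection_to_json

fx = reference_fixture()
closed = ak.saturate(fx.store, ak.default_ruleset())
query = ak.parse_query(tendon_insertion_query_text())

print(tendon_insertion_query_text())
table = ak.evaluate(query, closed)
print("answers (bones):")
print(table.to_tsv(closed.prefixes))

selection = select_objects(closed, mcf("id"), query)
print("scene selection driven by the answers:")
print(selection_to_json(selection, closed.prefixes))
print("the scene's tibia object is picked out; the muscle objects are not.")
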