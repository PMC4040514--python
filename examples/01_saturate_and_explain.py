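"""Forward-chain the core anatomy rules over the reference knowledge base.

Builds the packaged fixture, saturates it to its least fixpoint under the 11
core rules, and prints the proof tree for one inferred fact: that the
sartorius muscle contributes to the movement of the knee, derived by composing
"contributes to knee flexion" with "knee flexion is involved in knee movement".
"""

import anatokb as ak
from anatokb import schema as S
from anatokb.fixture import mcf, reference_fixture

fx = reference_fixture()
closed = ak.saturate(fx.store, ak.default_ruleset())

rep = closed.report
print(f"asserted facts : {rep.asserted_facts}")
print(f"inferred facts : {rep.inferred_facts} (in {rep.rounds} rounds)")
for rule_id, n in sorted(rep.inferred_by_rule.items()):
    print(f"  {rule_id:>4} -> {n} new fact(s)")

fact = ak.Triple(mcf("Sartorius"), S.CONTRIBUTESTO, mcf("Movement_of_knee"))
print(f"\nentailed: {fact in closed}  ({closed.prefixes.compact(fact.subject.value)}"
      f" contributes to {closed.prefixes.compact(fact.object.value)})")


def show(d: ak.Derivation, indent: int = 0) -> None:
    c = d.conclusion
    label = "asserted" if d.is_asserted() else f"by {d.rule_id}"
    print("  " * indent + f"{closed.prefixes.compact(c.subject.value)} "
          f"{closed.prefixes.compact(c.predicate.value)} "
          f"{closed.prefixes.compact(c.object.value)}  [{label}]")
    for p in d.premises:
        show(p, indent + 1)


print("\nproof tree:")
show(ak.explain(closed, fact))
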