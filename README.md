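# anatokb — a deductive anatomical knowledge base

`anatokb` is a small deductive RDF-style triple store for reasoning over
linked taxonomies of **anatomical entities** (knee, sartorius, tibia …),
**anatomical functions** (knee flexion, body stability …) and **3D content**
(scenes and mesh-backed objects).  It is aimed at people building anatomy
teaching tools, biomechanical simulation setups, or 3D medical viewers who
want to *select and validate* scene content by anatomical knowledge instead
of by geometry.

The knowledge is plain triples ⟨subject, predicate, object⟩ over a fixed
vocabulary: the taxonomy (`rdfs:subClassOf` with left/right specializations
`mcf:leftSubClassOf` / `mcf:rightSubClassOf`), the partonomy (`mcf:PartOf`),
attachment points (`mcf:InsertOn`), function structure (`mcf:IsInvolvedIn`)
and structure→function links (`mcf:hasFunction`, `mcf:contributesTo`), plus
scene relations (`mcf:Displays`, `mcf:Contains`, `mcf:Describes`,
`mcf:hasMesh`, …).

On top of the store sits a **safe-rule (Datalog) forward-chaining engine**.
A rule `IF ⟨body⟩ AND … THEN ⟨head⟩` is *safe* when every head variable
occurs in the body, which guarantees the saturation

&nbsp;&nbsp;&nbsp;&nbsp;*T*<sub>*i*+1</sub> = *T*<sub>*i*</sub> ∪ { head·σ : body·σ ⊆ *T*<sub>*i*</sub> }

reaches a finite least fixpoint.  The packaged core rule set has 11 rules:
transitivity of `subClassOf`, `PartOf` and `IsInvolvedIn` (R1–R3), relation
specializations (R4/R5: laterality links are subclass links; R6:
`hasFunction` ⊆ `contributesTo`) and five cross-relation compositions such as
R10 (`contributesTo ∘ IsInvolvedIn` → `contributesTo`) and R11
(`InsertOn ∘ PartOf` → `InsertOn`).  An optional twelfth rule colours every
3D object describing a bone subclass yellow.  Saturation is **semi-naive**
(each round only joins against the facts new in the previous round) and can
log a proof tree per derived fact.

Queries are the conjunctive SPARQL-SELECT subset with variables allowed in
*any* position, including the predicate, evaluated by natural join over the
saturated store.

## Worked example

The packaged reference fixture (57 triples: the knee-joint laterality pair,
the sartorius tendon insertion, the function taxonomy examples, a four-object
leg scene, and the muscle/knee-movement premises) drives the whole pipeline:

```python
import anatokb as ak
from anatokb.fixture import mcf, reference_fixture, tendon_insertion_query_text
from anatokb.scene import select_objects

fx = reference_fixture()
closed = ak.saturate(fx.store, ak.default_ruleset())
print(closed.report.asserted_facts, closed.report.inferred_facts)  # 57 20

table = ak.evaluate(ak.parse_query(tendon_insertion_query_text()), closed)
print(table.to_tsv(closed.prefixes))
# ?bone
# mcf:Medial_part_of_proximal_epiphysis_of_right_tibia
# mcf:Right_tibia

sel = select_objects(closed, mcf("id"), ak.parse_query(tendon_insertion_query_text()))
print(sel.ids())   # {'http://example.org/mcf#id4'}  — the tibia object, in yellow
```

Reading the numbers: saturation added 20 facts to the 57 asserted ones — among
them that all seven muscles of the worked example contribute to
`Movement_of_knee` (rule R10), and that the sartorius tendon, asserted to
insert on the *medial part of the proximal epiphysis of the right tibia*,
also inserts on the *right tibia* itself (rule R11 propagates insertions up
the partonomy).  The tendon-insertion query therefore returns two bones, and
the scene-selection step highlights the one scene object describing a bone.

The `examples/` directory holds one short script per capability
(saturation + proof trees, laterality expansion, query→scene selection,
constraint checking, synthetic ontologies); each prints the numbers above
with a line of interpretation.  The same workflows are available from the
shell via the `anatokb` command (`anatokb --help`).

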