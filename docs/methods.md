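# Methods

## Data model

Facts are ground triples ⟨subject, predicate, object⟩ with IRI subjects and
predicates and IRI-or-literal objects.  The store keeps set semantics (no
duplicates, no multiplicity) with three hash indexes (by subject, predicate,
object); a pattern match intersects the applicable index buckets and then
unifies, so repeated variables within a pattern bind consistently.

Deliberate restrictions: no blank nodes, no reification, no language tags or
datatyped literals — the anatomy vocabulary needs none of them.  `owl:sameAs`
links (used to record correspondences with FMA classes) are stored and
matchable but trigger **no** equality reasoning; this is a documented
limitation, not an oversight.  IRI comparison is case-sensitive, and local
names are kept verbatim (the vocabulary itself mixes conventions, e.g.
`knee_joint` vs `Knee`; two historical spellings of the laterality relations
differ only in case, and the lowercase forms used in the data triples are
canonical here).

Namespaces: the sources of the vocabulary never print full namespace IRIs, so
this package fixes `mcf: → http://example.org/mcf#` and
`fma: → http://example.org/fma#` alongside the standard W3C `rdf:`, `rdfs:`,
`owl:` namespaces.  The prefix table is extensible per document.

The 4×4 position matrix of a scene object is encoded as a literal of 16
whitespace-separated numbers (row-major).  The original encoding used by the
system this vocabulary models is not documented anywhere we could verify, so
this is a package-level convention.

## IO

N-Triples and a Turtle subset (`@prefix` declarations plus one
subject–predicate–object statement per line; no `;`/`,` sugar).  The readers
are line-oriented because the contracts here — document order preserved,
errors carrying line numbers, a *distinct* error for an undeclared prefix —
are not what a general-purpose RDF parser exposes; rdflib serves as the
independent grammar oracle in the test suite (it must parse our output to the
same fact set).  Writers sort statements by subject, predicate, object text,
so serialization is deterministic and injective on distinct stores.

## Rule engine

Rules are safe Datalog rules with single-atom heads over triple patterns;
variables may appear in any position, including the predicate.  Safety (head
variables ⊆ body variables) is checked at parse time and at rule-set
construction.

Saturation is **semi-naive**: round 1 evaluates every rule against the whole
store; from round 2 on, each rule is evaluated once per body-atom position
with that atom restricted to the facts derived in the previous round.  This
is the standard deductive-database optimization; the test suite and the
acceptance script verify set-equality with a naive re-evaluate-everything
fixpoint, and with a fully independent exhaustive-binding fixpoint at small
sizes.  Properties verified: idempotence, monotonicity under fact addition,
rule-order independence, and termination (safe rules over a finite constant
pool; an internal |constants|³·|predicates| cap exists purely as a safety
net and is unreachable for safe rules).

Derivation logging keeps the *first* derivation found per fact, tie-broken by
rule order then binding order; `explain` reconstructs the proof tree and
`replay` re-derives it bottom-up (soundness is tested for every fact of the
fixture closure).  `max_rounds` exhaustion raises an explicit
incomplete-closure error rather than returning a partial store.

## Laterality expansion

`expand_laterality(store, root)` collects the subtree of classes reaching
`root` over *asserted* `subClassOf` edges, then adds `Left_X leftSubClassOf
X` and `Right_X rightSubClassOf X` for every member and mirrors every stored
link whose predicate is in the policy set (default: `subClassOf`, `PartOf`,
`InsertOn`, `hasFunction`, `contributesTo`) **and whose endpoints are both in
the subtree** into each copy.  Boundary-crossing links are not replicated:
copying e.g. an `InsertOn` to a bone outside the subtree would silently
fabricate a left/right version of that outside bone.  The policy's predicate
set and prefixes are configurable for users who want wider replication.
Generated names prepend the prefix to the local name (`Left_knee_joint`),
matching the vocabulary's own examples.  A second expansion of the same root
raises a collision error instead of silently duplicating.

`subClassOf` is transitive but **not** reflexive here (the transitivity rule
is all the rule set states); queries needing reflexivity add the identity
binding themselves — the packaged tendon query, for instance, names the
right sartorius through its `rightSubClassOf` specialization rather than
relying on `Sartorius ⊑ Sartorius`.

## Queries

The SELECT/WHERE basic-graph-pattern subset with `PREFIX` headers; no
OPTIONAL/FILTER/UNION/property paths — saturation replaces property paths for
this vocabulary (e.g. the transitive closure of `PartOf` is materialized, so
a single pattern reaches it).  DISTINCT is always on, mirroring the store's
set semantics; the keyword is accepted for compatibility.  Evaluation is a
nested-loop join that greedily picks the cheapest remaining pattern (fewest
index matches under the current binding); correctness is defined by — and
tested against — an exhaustive variable-assignment oracle and rdflib's SPARQL
engine, not by the plan.  Rows are sorted lexicographically, so answer tables
are deterministic.

## Constraints and scene validity

A constraint `IF body REQUIRE atoms` flags every distinct body binding for
which the requirement atoms are jointly unsatisfiable (requirement-only
variables are existential).  The requirement is a conjunction rather than a
single atom because the canonical example — every sinovial joint has an
articular capsule *that is part of it* — needs two atoms.  Checking is
existential only, not cardinality-aware.

Scene validity: every contained object's described entity must equal the
displayed entity or reach it along entailed `subClassOf` ∪ `PartOf` edges,
in either direction of specialization — a Leg scene admits parts of the leg
and their left/right specializations (the mixed path
`Left_sartorius ⊑ Sartorius PartOf Leg` is a reachability question, not a
single entailed edge, hence the graph search over the closure).  For scenes
displaying a *function*, validity is an extension: the described entity must
`hasFunction`/`contributesTo` the displayed function in the closure.

Mesh and texture files are referenced by path only and never parsed;
identification of 3D content is deliberately decoupled from its storage.

## Reference fixture

The packaged fixture (57 triples) carries a provenance tag per triple:
`printed` (stated as explicit triples in the source material this vocabulary
models), `prose` (stated in its running text: the seven-muscle worked
example), and `connective` (glue added by this package: tendon/sartorius
links, tibia partonomy, Bone superclass links, leg partonomy of the scene's
muscles, the knee-joint subtree content, and one bone object in the scene —
the printed scene block lists three muscle objects and is explicitly
elided, while the query workflow highlights bones, so a tibia object is
needed for the selection step to have a witness).  Each connective triple is
the minimum needed to make a documented workflow executable.  The fixture is
deterministic; `knee_joint_subtree()` additionally exposes the knee-joint
subtree *without* its laterality triples, since the main fixture already
contains them and re-expanding there collides by design.

## Synthetic generator

`generate_synthetic_ontology` emulates the gross shape of an anatomical
knowledge base for property tests: a subclass tree (default depth 3,
branching 2) anchored under the Anatomical-entity top class; per-node
Bernoulli edges for `PartOf` (0.3, to an earlier node — keeping the
partonomy acyclic), `InsertOn` (0.15), `hasFunction`/`contributesTo` (0.2
each, to a random function); a function forest over `IsInvolvedIn` (0.5);
and laterality expansion of a fraction (0.25) of the depth-1 subtrees.  The
defaults are chosen so that every core rule fires regularly at a store size
(tens to ~200 triples) where the exhaustive oracles remain affordable; they
make no claim of statistical fidelity to any real ontology's distribution
(in particular not to a ~74 000-class production taxonomy), so passing
property tests demonstrate engine correctness, not realism of content.
Everything derives from one integer seed; names are counter-based so
serializations are byte-identical across runs.

## Problem sizes

The equivalence and invariant checks run at sizes where the independent
oracles are exact and fast: random stores of up to 150 triples over 14
entities for the semi-naive/naive comparison (100 seeds), up to ~30 triples
over 5–6 entities where an exhaustive assignment enumeration is the oracle,
100 synthetic ontologies (default parameters) for the global inclusion
invariant, and the 57-triple fixture for all worked examples.  These sizes
were chosen so each oracle stays brute-force-honest; the engine itself has
no size-dependent code paths.

## Known limitations

- No equality reasoning over `owl:sameAs`; no negation, built-ins or
  existential-head rules; no stratification (nothing needs it).
- No OWL/description-logic reasoning; this is deliberately the
  rule-plus-RDF(S) fragment.
- Incremental maintenance under *deletion* is unsupported: delete and
  re-saturate.
- Constraint checking is existential, not cardinality-aware.
- Full RDF 1.1 / SPARQL 1.1 conformance is a non-goal; the dialects are the
  documented subsets.
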