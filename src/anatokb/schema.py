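"""Anatomy vocabulary, the default rule set, laterality expansion, and
constraint-based model checking.

The knowledge base links three taxonomies — anatomical entities, anatomical
functions, and 3D content — through a small fixed vocabulary of relations.
Laterality expansion generates the ``Left_``/``Right_`` specializations of an
anatomical subtree; constraints express existential well-formedness
requirements ("every sinovial joint has an articular capsule") checked against
the saturated store.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

from .model import DEFAULT_PREFIXES, Pattern, PrefixTable, Term, TripleStore, Triple, iri, var
from .rules import RuleSet, RuleSyntaxError, match_body, parse_rules, _parse_atoms

_MCF = DEFAULT_PREFIXES["mcf"]
_RDF = DEFAULT_PREFIXES["rdf"]
_RDFS = DEFAULT_PREFIXES["rdfs"]
_OWL = DEFAULT_PREFIXES["owl"]

# Generic RDF/OWL properties.
RDF_TYPE = iri(_RDF + "type")
SUBCLASSOF = iri(_RDFS + "subClassOf")
SAMEAS = iri(_OWL + "sameAs")

# Anatomical structure relations.
LEFT_SUBCLASSOF = iri(_MCF + "leftSubClassOf")
RIGHT_SUBCLASSOF = iri(_MCF + "rightSubClassOf")
PARTOF = iri(_MCF + "PartOf")
INSERTON = iri(_MCF + "InsertOn")

# Function linkage relations.
ISINVOLVEDIN = iri(_MCF + "IsInvolvedIn")
HASFUNCTION = iri(_MCF + "hasFunction")
CONTRIBUTESTO = iri(_MCF + "contributesTo")

# 3D content relations.
CONTAINS = iri(_MCF + "Contains")
DESCRIBES = iri(_MCF + "Describes")
DISPLAYS = iri(_MCF + "Displays")
POSITION = iri(_MCF + "Position")
HASMESH = iri(_MCF + "hasMesh")
HASTEXTURE = iri(_MCF + "hasTexture")
HASCOLOUR = iri(_MCF + "hasColour")

#: The 15 domain relations (the two generic properties above stand apart).
RELATIONS: tuple[Term, ...] = (
    SUBCLASSOF,
    LEFT_SUBCLASSOF,
    RIGHT_SUBCLASSOF,
    PARTOF,
    INSERTON,
    ISINVOLVEDIN,
    HASFUNCTION,
    CONTRIBUTESTO,
    CONTAINS,
    DESCRIBES,
    DISPLAYS,
    POSITION,
    HASMESH,
    HASTEXTURE,
    HASCOLOUR,
)

# Top classes of the three taxonomies, plus the two 3D content classes.
ANATOMICAL_ENTITY = iri(_MCF + "Anatomical_entity")
FUNCTIONAL_ENTITY = iri(_MCF + "Functional_entity")
ENTITY_3D = iri(_MCF + "3D-entity")
SCENE_3D = iri(_MCF + "3D-scene")
OBJECT_3D = iri(_MCF + "3D-object")

CLASSES: tuple[Term, ...] = (ANATOMICAL_ENTITY, FUNCTIONAL_ENTITY, ENTITY_3D, SCENE_3D, OBJECT_3D)


def _load_rule_file(name: str) -> str:
    return resources.files("anatokb.data").joinpath(name).read_text(encoding="utf-8")


def default_ruleset(include_colour_rule: bool = False) -> RuleSet:
    """The packaged core rule set (11 rules), optionally plus the bone-colour rule.

    The core covers three transitivity rules (subClassOf, PartOf,
    IsInvolvedIn), three relation specializations (leftSubClassOf and
    rightSubClassOf into subClassOf; hasFunction into contributesTo) and five
    cross-relation rules.  The colour rule paints 3D objects that describe
    bone subclasses yellow.
    """
    text = _load_rule_file("anatomy_core.rules")
    if include_colour_rule:
        text += _load_rule_file("bone_colour.rules")
    return parse_rules(text)


# -- laterality -------------------------------------------------------------


class LateralityError(ValueError):
    pass


class LateralityCollisionError(LateralityError):
    """A generated Left_/Right_ name already exists in the store."""


@dataclass(frozen=True)
class LateralityPolicy:
    """How laterality expansion names its copies and which links it replicates.

    Only links with BOTH endpoints inside the expanded subtree are replicated;
    widening ``replicated`` is the supported way to copy more relation kinds.
    """

    left_prefix: str = "Left_"
    right_prefix: str = "Right_"
    replicated: frozenset[Term] = frozenset(
        (SUBCLASSOF, PARTOF, INSERTON, HASFUNCTION, CONTRIBUTESTO)
    )

    def __post_init__(self) -> None:
        if not self.left_prefix or not self.right_prefix:
            raise ValueError("laterality prefixes must be non-empty")
        if self.left_prefix == self.right_prefix:
            raise ValueError("laterality prefixes must be distinct")
        if not self.replicated:
            raise ValueError("replicated predicate set must be non-empty")


def _prefixed(term: Term, prefix: str) -> Term:
    """Prepend ``prefix`` to the local name (the part after '#' or last '/')."""
    value = term.value
    cut = max(value.rfind("#"), value.rfind("/")) + 1
    return iri(value[:cut] + prefix + value[cut:])


def subclass_subtree(store: TripleStore, root: Term) -> set[Term]:
    """``root`` plus everything reaching it along asserted subClassOf edges."""
    seen = {root}
    frontier = [root]
    while frontier:
        node = frontier.pop()
        for t in store.match((var("x"), SUBCLASSOF, node)):
            if t.subject not in seen:
                seen.add(t.subject)
                frontier.append(t.subject)
    return seen


def expand_laterality(
    store: TripleStore, root: Term, policy: LateralityPolicy | None = None
) -> TripleStore:
    """Add Left_/Right_ specializations of the subtree rooted at ``root``.

    For each member X of the subClassOf subtree below ``root`` (inclusive),
    adds ``Left_X leftSubClassOf X`` and ``Right_X rightSubClassOf X``; every
    stored link ``(a p b)`` with ``p`` in the policy's replicated set and both
    endpoints in the subtree is mirrored into both copies.  The original
    subtree is left untouched.  Returns a new store.

    Raises :class:`LateralityError` if the root is absent and
    :class:`LateralityCollisionError` if any generated name already occurs in
    the store (so running the expansion twice fails loudly instead of
    silently duplicating).
    """
    policy = policy or LateralityPolicy()
    present = {t for fact in store for t in fact}
    if root not in present:
        raise LateralityError(f"root {root} not present in store")
    members = subclass_subtree(store, root)
    mapping = {
        side: {m: _prefixed(m, prefix) for m in members}
        for side, prefix in (("left", policy.left_prefix), ("right", policy.right_prefix))
    }
    collisions = sorted(
        t.value for side in mapping.values() for t in side.values() if t in present
    )
    if collisions:
        raise LateralityCollisionError(f"generated names already present: {collisions}")

    out = store.copy()
    for m in members:
        out.add(Triple(mapping["left"][m], LEFT_SUBCLASSOF, m))
        out.add(Triple(mapping["right"][m], RIGHT_SUBCLASSOF, m))
    for fact in store:
        if fact.predicate in policy.replicated and fact.subject in members and fact.object in members:
            for side in ("left", "right"):
                ren = mapping[side]
                out.add(Triple(ren[fact.subject], fact.predicate, ren[fact.object]))
    return out


# -- constraint checking ----------------------------------------------------


@dataclass(frozen=True)
class ConstraintRule:
    """Existential constraint: for every body binding, the requirement atoms
    must be jointly satisfiable (requirement-only variables are existential)."""

    id: str
    body: tuple[Pattern, ...]
    requirement: tuple[Pattern, ...]


@dataclass(frozen=True)
class Violation:
    constraint_id: str
    binding: tuple[tuple[str, str], ...]  # sorted (variable, value) pairs

    def __str__(self) -> str:
        bound = ", ".join(f"?{k}={v}" for k, v in self.binding)
        return f"{self.constraint_id}: no satisfying instance for {bound}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)


_CONSTRAINT_LINE = re.compile(
    r"(?P<id>[\w.-]+)\s*:\s*IF\s+(?P<body>.+?)\s+REQUIRE\s+(?P<req>.+)$", re.IGNORECASE
)


def parse_constraints(text: str, prefixes: PrefixTable | None = None) -> list[ConstraintRule]:
    """Parse constraint lines: ``Cid: IF (s p o) [AND ...]* REQUIRE (s p o) [AND ...]*``."""
    table = prefixes if prefixes is not None else PrefixTable()
    out: list[ConstraintRule] = []
    index = 0
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        index += 1
        m = _CONSTRAINT_LINE.match(line)
        if m is None:
            raise RuleSyntaxError("expected 'Cid: IF (s p o) ... REQUIRE (s p o) ...'", index)
        out.append(
            ConstraintRule(
                m.group("id"),
                tuple(_parse_atoms(m.group("body"), table, index)),
                tuple(_parse_atoms(m.group("req"), table, index)),
            )
        )
    return out


def default_constraints() -> list[ConstraintRule]:
    return parse_constraints(_load_rule_file("sinovial_capsule.constraints"))


def validate_model(closed: TripleStore, constraints: list[ConstraintRule]) -> ValidationReport:
    """Check every constraint against (entailed) facts of ``closed``.

    For each distinct body binding with no satisfying requirement instance,
    the report carries one violation naming the binding.  Empty report means
    the model is valid.  Intended to run on a saturated store.
    """
    report = ValidationReport()
    for c in constraints:
        seen: set[tuple] = set()
        for binding in match_body(closed, c.body):
            key = tuple(sorted((k, v.value) for k, v in binding.items()))
            if key in seen:
                continue
            seen.add(key)
            satisfied = next(iter(match_body(closed, c.requirement, binding)), None)
            if satisfied is None:
                report.violations.append(Violation(c.id, key))
    report.violations.sort(key=lambda v: (v.constraint_id, v.binding))
    return report
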