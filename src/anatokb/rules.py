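"""Safe-rule (Datalog) model, parser, safety checking, and saturation.

A rule is ``IF body-atom (AND body-atom)* THEN head-atom`` where every atom is
a triple pattern.  Safety — every head variable occurs in some body atom —
guarantees that forward chaining terminates: all derivable facts are built
from the finite set of constants already in the store.

Saturation uses semi-naive evaluation: after the first round, a rule only
fires on instantiations in which at least one body atom matches a fact derived
in the previous round.  The result is the same least fixpoint as naive
re-evaluation (the test suite checks this against a naive oracle), reached in
polynomially fewer join probes.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .model import (
    Pattern,
    PrefixTable,
    Term,
    Triple,
    TripleStore,
    iri,
    lit,
    pattern_vars,
    substitute,
    unify,
    var,
)

ASSERTED = "asserted"


class RuleSyntaxError(ValueError):
    """Malformed rule text; carries the 1-based rule index in the document."""

    def __init__(self, message: str, index: int):
        super().__init__(f"rule {index}: {message}")
        self.index = index


class UnsafeRuleError(ValueError):
    """A head variable does not occur in any body atom."""

    def __init__(self, rule_id: str, variables: Sequence[str]):
        names = ", ".join("?" + v for v in sorted(variables))
        super().__init__(f"rule {rule_id} is unsafe: head variable(s) {names} unbound in body")
        self.rule_id = rule_id
        self.variables = tuple(sorted(variables))


class NotEntailedError(LookupError):
    """The fact is not in the closure, so it has no derivation."""


class IncompleteClosureError(RuntimeError):
    """max_rounds was exhausted before the fixpoint was reached."""


@dataclass(frozen=True)
class Rule:
    """A safe rule: conjunctive body, single-atom head."""

    id: str
    body: tuple[Pattern, ...]
    head: Pattern

    def __post_init__(self) -> None:
        if not self.body:
            raise ValueError(f"rule {self.id}: empty body")

    def head_vars(self) -> set[str]:
        return pattern_vars(self.head)

    def body_vars(self) -> set[str]:
        out: set[str] = set()
        for atom in self.body:
            out |= pattern_vars(atom)
        return out


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[Rule, ...]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate rule ids")
        for r in self.rules:
            violations = check_safety(r)
            if violations:
                raise UnsafeRuleError(r.id, violations)

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def __getitem__(self, rule_id: str) -> Rule:
        for r in self.rules:
            if r.id == rule_id:
                return r
        raise KeyError(rule_id)


def check_safety(rule: Rule) -> list[str]:
    """Names of head variables not bound by the body (empty list = safe)."""
    return sorted(rule.head_vars() - rule.body_vars())


# -- rule text --------------------------------------------------------------
#
# One rule per line:  Rid: IF (s p o) AND (s p o) THEN (s p o)
# Terms are prefixed names, <full iris>, "literals", or ?variables.
# '#' starts a comment.

_ATOM = re.compile(r"\(\s*(\S+)\s+(\S+)\s+((?:\"(?:[^\"\\]|\\.)*\")|\S+)\s*\)")
_RULE_LINE = re.compile(r"(?P<id>[\w.-]+)\s*:\s*IF\s+(?P<body>.+?)\s+THEN\s+(?P<head>.+)$", re.IGNORECASE)


def _parse_term(text: str, prefixes: PrefixTable, index: int) -> Term:
    if text.startswith("?"):
        name = text[1:]
        if not name:
            raise RuleSyntaxError("empty variable name", index)
        return var(name)
    if text.startswith('"') and text.endswith('"') and len(text) >= 2:
        return lit(text[1:-1].replace('\\"', '"').replace("\\\\", "\\"))
    if text.startswith("<") and text.endswith(">"):
        return iri(text[1:-1])
    if ":" in text:
        try:
            return iri(prefixes.expand(text))
        except KeyError:
            raise RuleSyntaxError(f"unknown prefix in {text!r}", index) from None
    raise RuleSyntaxError(f"cannot parse term {text!r}", index)


def _parse_atoms(text: str, prefixes: PrefixTable, index: int) -> list[Pattern]:
    atoms: list[Pattern] = []
    rest = text.strip()
    while rest:
        m = _ATOM.match(rest)
        if m is None:
            raise RuleSyntaxError(f"expected '(s p o)' near {rest[:30]!r}", index)
        atoms.append(tuple(_parse_term(g, prefixes, index) for g in m.groups()))  # type: ignore[arg-type]
        rest = rest[m.end():].strip()
        if rest:
            if not rest.upper().startswith("AND"):
                raise RuleSyntaxError(f"expected AND between atoms near {rest[:30]!r}", index)
            rest = rest[3:].strip()
    if not atoms:
        raise RuleSyntaxError("no atoms", index)
    return atoms


def parse_rules(text: str, prefixes: PrefixTable | None = None) -> RuleSet:
    """Parse a rule document (one rule per line) into a RuleSet.

    Safety is checked at parse time: an unsafe rule raises
    :class:`UnsafeRuleError` naming the offending head variable(s).
    """
    table = prefixes if prefixes is not None else PrefixTable()
    rules: list[Rule] = []
    index = 0
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        index += 1
        m = _RULE_LINE.match(line)
        if m is None:
            raise RuleSyntaxError("expected 'Rid: IF (s p o) [AND (s p o)]* THEN (s p o)'", index)
        body = _parse_atoms(m.group("body"), table, index)
        heads = _parse_atoms(m.group("head"), table, index)
        if len(heads) != 1:
            raise RuleSyntaxError("exactly one head atom expected", index)
        rules.append(Rule(m.group("id"), tuple(body), heads[0]))
    return RuleSet(tuple(rules))


def _format_term(t: Term, prefixes: PrefixTable) -> str:
    if t.is_var:
        return "?" + t.value
    if t.kind == "literal":
        return '"%s"' % t.value.replace("\\", "\\\\").replace('"', '\\"')
    compact = prefixes.compact(t.value)
    return compact if compact != t.value else f"<{t.value}>"


def format_rules(ruleset: RuleSet, prefixes: PrefixTable | None = None) -> str:
    """Render a RuleSet back to rule-file text (inverse of parse_rules)."""
    table = prefixes if prefixes is not None else PrefixTable()

    def atom(p: Pattern) -> str:
        return "(" + " ".join(_format_term(t, table) for t in p) + ")"

    lines = [
        f"{r.id}: IF {' AND '.join(atom(a) for a in r.body)} THEN {atom(r.head)}"
        for r in ruleset
    ]
    return "\n".join(lines) + "\n"


# -- evaluation -------------------------------------------------------------


def match_body(
    store: TripleStore,
    atoms: Sequence[Pattern],
    binding: Mapping[str, Term] | None = None,
    *,
    restrict: tuple[int, "TripleStore"] | None = None,
) -> Iterable[dict[str, Term]]:
    """All bindings of ``atoms`` against ``store`` extending ``binding``.

    With ``restrict=(i, delta)``, atom ``i`` is matched against ``delta``
    instead of ``store`` — the semi-naive trick.  Atoms are matched
    left-to-right, each instantiated with the bindings accumulated so far.
    """
    partial = dict(binding or {})

    def rec(i: int, bound: dict[str, Term]) -> Iterable[dict[str, Term]]:
        if i == len(atoms):
            yield bound
            return
        source = restrict[1] if restrict is not None and restrict[0] == i else store
        pat = substitute(atoms[i], bound)
        for fact in source.match(pat):
            ext = unify(pat, fact)
            if ext is None:  # pragma: no cover - match already guarantees this
                continue
            merged = dict(bound)
            merged.update(ext)
            yield from rec(i + 1, merged)

    yield from rec(0, partial)


def _instantiate_head(rule: Rule, binding: Mapping[str, Term]) -> Triple:
    s, p, o = substitute(rule.head, binding)
    return Triple(s, p, o)


def apply_rule(store: TripleStore, rule: Rule) -> set[Triple]:
    """One-shot application: new head instances not already in the store."""
    if check_safety(rule):
        raise UnsafeRuleError(rule.id, check_safety(rule))
    out: set[Triple] = set()
    for binding in match_body(store, rule.body):
        fact = _instantiate_head(rule, binding)
        if fact not in store:
            out.add(fact)
    return out


@dataclass(frozen=True)
class Derivation:
    """Proof tree for one fact: leaves are asserted, internal nodes cite a rule."""

    conclusion: Triple
    rule_id: str  # a rule id, or "asserted"
    premises: tuple["Derivation", ...] = ()

    def is_asserted(self) -> bool:
        return self.rule_id == ASSERTED


@dataclass
class SaturationReport:
    """What a saturation run did: rounds and per-rule inferred-fact counts."""

    rounds: int = 0
    inferred_by_rule: dict[str, int] = field(default_factory=dict)
    asserted_facts: int = 0
    inferred_facts: int = 0

    def total_inferred(self) -> int:
        return sum(self.inferred_by_rule.values())


class ClosedStore(TripleStore):
    """A saturated store carrying its run report and (optionally) a proof log."""

    def __init__(self, facts=(), prefixes=None):
        super().__init__(facts, prefixes)
        self.report = SaturationReport()
        self.proofs: dict[Triple, tuple[str, tuple[Triple, ...]]] = {}
        self.ruleset: RuleSet | None = None


def saturate(
    store: TripleStore,
    ruleset: RuleSet,
    max_rounds: int | None = None,
    *,
    log_derivations: bool = True,
) -> ClosedStore:
    """Forward-chain ``ruleset`` over ``store`` to the least fixpoint.

    Returns a new :class:`ClosedStore` containing the input plus everything
    derivable; the input store is not modified.  Raises
    :class:`IncompleteClosureError` if ``max_rounds`` is hit first (cannot
    happen with ``max_rounds=None`` on safe rules).  The proof log keeps the
    first derivation found per fact, tie-broken by rule order then by the
    sorted premise bindings.
    """
    closed = ClosedStore(store, dict(store.prefixes._map))
    closed.ruleset = ruleset
    closed.report.asserted_facts = len(closed)
    if log_derivations:
        for fact in closed:
            closed.proofs[fact] = (ASSERTED, ())

    # Safety bound: every derivable fact draws its terms from the finite
    # constant pool, so |constants|^3 * |predicates| caps the closure size.
    constants = {t for fact in closed for t in fact} | {
        t for r in ruleset for atom in (*r.body, r.head) for t in atom if not t.is_var
    }
    predicates = {fact.predicate for fact in closed} | {
        r.head[1] for r in ruleset if not r.head[1].is_var
    }
    hard_cap = max(1, len(constants)) ** 3 * max(1, len(predicates))

    delta = TripleStore(closed)
    rounds = 0
    while len(delta):
        if max_rounds is not None and rounds >= max_rounds:
            raise IncompleteClosureError(
                f"fixpoint not reached within {max_rounds} rounds ({len(delta)} facts pending)"
            )
        if rounds > hard_cap:  # pragma: no cover - safety net, unreachable on safe rules
            raise IncompleteClosureError("internal termination bound exceeded")
        rounds += 1
        new_delta = TripleStore()
        for rule in ruleset:
            n_atoms = len(rule.body)
            sources = range(n_atoms) if rounds > 1 else (0,)
            seen_bindings: set[tuple] = set()
            for i in sources:
                restrict = (i, delta) if rounds > 1 else None
                # Round 1 matches everything (delta == whole store), so a
                # single unrestricted pass suffices.
                for binding in match_body(closed, rule.body, restrict=restrict):
                    key = tuple(sorted((k, v) for k, v in binding.items()))
                    if key in seen_bindings:
                        continue
                    seen_bindings.add(key)
                    fact = _instantiate_head(rule, binding)
                    if fact in closed or fact in new_delta:
                        continue
                    new_delta.add(fact)
                    closed.report.inferred_by_rule[rule.id] = (
                        closed.report.inferred_by_rule.get(rule.id, 0) + 1
                    )
                    if log_derivations:
                        premises = tuple(
                            Triple(*substitute(atom, binding)) for atom in rule.body
                        )
                        closed.proofs[fact] = (rule.id, premises)
        closed.update(new_delta)
        delta = new_delta
    closed.report.rounds = rounds
    closed.report.inferred_facts = len(closed) - closed.report.asserted_facts
    return closed


def naive_fixpoint(store: TripleStore, ruleset: RuleSet) -> TripleStore:
    """Naive re-evaluate-everything fixpoint (reference implementation).

    Kept in the library (not just tests) so callers can cross-check the
    semi-naive engine on small inputs.
    """
    closed = store.copy()
    while True:
        new = set()
        for rule in ruleset:
            new |= apply_rule(closed, rule)
        if not new:
            return closed
        closed.update(new)


def explain(closed: ClosedStore, fact: Triple) -> Derivation:
    """Proof tree for ``fact`` from the saturation's derivation log."""
    if fact not in closed:
        raise NotEntailedError(f"not entailed: {fact}")
    if not closed.proofs:
        raise ValueError("saturation ran without derivation logging")
    rule_id, premises = closed.proofs[fact]
    if rule_id == ASSERTED:
        return Derivation(fact, ASSERTED)
    return Derivation(fact, rule_id, tuple(explain(closed, p) for p in premises))


def replay(derivation: Derivation, ruleset: RuleSet, asserted: TripleStore) -> bool:
    """Re-derive a proof tree bottom-up; True iff every step checks out."""
    if derivation.is_asserted():
        return derivation.conclusion in asserted
    rule = ruleset[derivation.rule_id]
    if len(rule.body) != len(derivation.premises):
        return False
    binding: dict[str, Term] = {}
    for atom, premise in zip(rule.body, derivation.premises):
        ext = unify(substitute(atom, binding), premise.conclusion)
        if ext is None:
            return False
        binding.update(ext)
        if not replay(premise, ruleset, asserted):
            return False
    return _instantiate_head(rule, binding) == derivation.conclusion
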