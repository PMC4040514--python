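"""Independent reference implementations used only for cross-checking.

Deliberately written without the package's matching/join machinery: matching
is a position-by-position scan, rule application enumerates candidate
bindings exhaustively, and closures come from networkx.  Slow but obviously
correct on small inputs.
"""

from __future__ import annotations

import itertools

import networkx as nx

from anatokb.model import Term, Triple


def scan_match(facts, pattern) -> list[Triple]:
    """Linear-scan unification: no indexes, no shared code with the store."""
    out = []
    for f in facts:
        binding = {}
        ok = True
        for p, t in zip(pattern, (f.subject, f.predicate, f.object)):
            if p.kind == "variable":
                if p.value in binding and binding[p.value] != t:
                    ok = False
                    break
                binding[p.value] = t
            elif p != t:
                ok = False
                break
        if ok:
            out.append(f)
    return out


def _ground(pattern, binding):
    return tuple(binding[t.value] if t.kind == "variable" else t for t in pattern)


def _satisfied(facts, atom, binding):
    s, p, o = _ground(atom, binding)
    return Triple(s, p, o) in facts


def exhaustive_rule_application(facts: set[Triple], rule) -> set[Triple]:
    """Every head instance over ALL assignments of rule variables to store
    terms whose body is fully satisfied; minus facts already present."""
    terms = sorted(
        {t for f in facts for t in (f.subject, f.predicate, f.object)},
        key=lambda t: (t.kind, t.value),
    )
    variables = sorted(
        {t.value for atom in (*rule.body, rule.head) for t in atom if t.kind == "variable"}
    )
    new = set()
    for combo in itertools.product(terms, repeat=len(variables)):
        binding = dict(zip(variables, combo))
        try:
            if all(_satisfied(facts, atom, binding) for atom in rule.body):
                s, p, o = _ground(rule.head, binding)
                head = Triple(s, p, o)
                if head not in facts:
                    new.add(head)
        except ValueError:
            continue  # ill-typed head instantiation (e.g. literal subject)
    return new


def exhaustive_fixpoint(facts: set[Triple], rules) -> set[Triple]:
    """Naive fixpoint over exhaustive_rule_application."""
    closed = set(facts)
    while True:
        new = set()
        for r in rules:
            new |= exhaustive_rule_application(closed, r)
        if not new:
            return closed
        closed |= new


def exhaustive_query(facts: set[Triple], query) -> set[tuple[Term, ...]]:
    """All projections over ALL assignments of query variables to store terms."""
    terms = sorted(
        {t for f in facts for t in (f.subject, f.predicate, f.object)},
        key=lambda t: (t.kind, t.value),
    )
    variables = sorted(
        {t.value for p in query.patterns for t in p if t.kind == "variable"}
    )
    out = set()
    for combo in itertools.product(terms, repeat=len(variables)):
        binding = dict(zip(variables, combo))
        try:
            if all(_satisfied(facts, p, binding) for p in query.patterns):
                out.add(tuple(binding[v] for v in query.projected))
        except ValueError:
            continue
    return out


def transitive_closure_pairs(facts, predicate: Term) -> set[tuple[str, str]]:
    """Transitive closure of one relation's asserted edges, via networkx."""
    g = nx.DiGraph()
    for f in facts:
        if f.predicate == predicate:
            g.add_edge(f.subject.value, f.object.value)
    tc = nx.transitive_closure(g)
    return set(tc.edges())


def relation_pairs(facts, predicate: Term) -> set[tuple[str, str]]:
    return {(f.subject.value, f.object.value) for f in facts if f.predicate == predicate}


def exhaustive_constraint_violations(facts: set[Triple], constraint) -> set[tuple]:
    """Body bindings with no satisfying requirement instance, by enumerating
    ALL assignments of constraint variables to store terms."""
    terms = sorted(
        {t for f in facts for t in (f.subject, f.predicate, f.object)},
        key=lambda t: (t.kind, t.value),
    )
    body_vars = sorted({t.value for atom in constraint.body for t in atom if t.kind == "variable"})
    req_only = sorted(
        {t.value for atom in constraint.requirement for t in atom if t.kind == "variable"}
        - set(body_vars)
    )
    violations = set()
    for combo in itertools.product(terms, repeat=len(body_vars)):
        binding = dict(zip(body_vars, combo))
        try:
            if not all(_satisfied(facts, atom, binding) for atom in constraint.body):
                continue
        except ValueError:
            continue
        satisfiable = False
        for ext in itertools.product(terms, repeat=len(req_only)):
            full = {**binding, **dict(zip(req_only, ext))}
            try:
                if all(_satisfied(facts, atom, full) for atom in constraint.requirement):
                    satisfiable = True
                    break
            except ValueError:
                continue
        if not satisfiable:
            violations.add(tuple(sorted((k, v.value) for k, v in binding.items())))
    return violations
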