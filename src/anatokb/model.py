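"""Core triple data model: terms, triples, prefix tables, and an indexed store.

Facts are RDF-style triples ``(subject, predicate, object)`` where subject and
predicate are IRIs and the object is an IRI or a plain literal.  Patterns are
triples that may additionally contain variables (``?x``) in any position —
including the predicate, which is what lets queries and rules range over the
relations themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

IRI = "iri"
LITERAL = "literal"
VARIABLE = "variable"

#: Default prefix table.  The anatomy vocabulary lives under ``mcf:``; links to
#: the Foundational Model of Anatomy use ``fma:``.  Namespace strings are this
#: package's own choice (documented in docs/methods.md).
DEFAULT_PREFIXES: dict[str, str] = {
    "mcf": "http://example.org/mcf#",
    "fma": "http://example.org/fma#",
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "owl": "http://www.w3.org/2002/07/owl#",
}


@dataclass(frozen=True, slots=True)
class Term:
    """An IRI, a plain literal, or a variable.

    ``value`` holds the full IRI text, the literal's lexical form, or the
    variable name without the leading ``?``.
    """

    kind: str
    value: str

    def __post_init__(self) -> None:
        if self.kind not in (IRI, LITERAL, VARIABLE):
            raise ValueError(f"unknown term kind: {self.kind!r}")
        if not self.value:
            raise ValueError("empty term value")

    @property
    def is_var(self) -> bool:
        return self.kind == VARIABLE

    def __str__(self) -> str:
        if self.kind == VARIABLE:
            return "?" + self.value
        if self.kind == LITERAL:
            return '"%s"' % self.value.replace("\\", "\\\\").replace('"', '\\"')
        return f"<{self.value}>"


def iri(value: str) -> Term:
    return Term(IRI, value)


def lit(value: str) -> Term:
    return Term(LITERAL, value)


def var(name: str) -> Term:
    return Term(VARIABLE, name.lstrip("?"))


@dataclass(frozen=True, slots=True)
class Triple:
    """A ground fact.  No variables allowed in any position."""

    subject: Term
    predicate: Term
    object: Term

    def __post_init__(self) -> None:
        if self.subject.kind != IRI:
            raise ValueError(f"triple subject must be an iri, got {self.subject}")
        if self.predicate.kind != IRI:
            raise ValueError(f"triple predicate must be an iri, got {self.predicate}")
        if self.object.kind == VARIABLE:
            raise ValueError("triple object must be ground (iri or literal)")

    def __iter__(self) -> Iterator[Term]:
        return iter((self.subject, self.predicate, self.object))

    def __str__(self) -> str:
        return f"({self.subject} {self.predicate} {self.object})"


Pattern = tuple[Term, Term, Term]
"""A triple pattern: three terms, variables allowed anywhere."""


def sort_key(t: Triple) -> tuple[str, str, str]:
    return (t.subject.value, t.predicate.value, t.object.value)


class PrefixTable:
    """Bidirectional prefixed-name <-> full-IRI mapping.

    Expansion/compaction is lossless: ``compact(expand(x)) == x`` whenever a
    prefix covers the namespace, and the longest matching namespace wins.
    """

    def __init__(self, prefixes: Mapping[str, str] | None = None):
        self._map: dict[str, str] = dict(DEFAULT_PREFIXES if prefixes is None else prefixes)

    def bind(self, prefix: str, namespace: str) -> None:
        self._map[prefix] = namespace

    def items(self) -> list[tuple[str, str]]:
        return sorted(self._map.items())

    def expand(self, qname: str) -> str:
        """``mcf:Knee`` -> full IRI.  Raises KeyError for unknown prefixes."""
        prefix, _, local = qname.partition(":")
        if prefix not in self._map:
            raise KeyError(prefix)
        return self._map[prefix] + local

    def compact(self, full: str) -> str:
        """Full IRI -> prefixed name where possible, else the IRI unchanged."""
        best: tuple[int, str] | None = None
        for prefix, ns in self._map.items():
            if full.startswith(ns) and (best is None or len(ns) > best[0]):
                best = (len(ns), prefix)
        if best is None:
            return full
        _, prefix = best
        return f"{prefix}:{full[len(self._map[prefix]):]}"


class TripleStore:
    """A set of ground triples with subject/predicate/object indexes.

    Set semantics throughout: adding a present triple is a no-op, the
    all-variable pattern matches every fact exactly once, and the indexes are
    kept exactly consistent with the fact set.
    """

    def __init__(
        self,
        facts: Iterable[Triple] = (),
        prefixes: Mapping[str, str] | None = None,
    ):
        self.prefixes = PrefixTable(prefixes)
        self._facts: set[Triple] = set()
        self._by_s: dict[Term, set[Triple]] = {}
        self._by_p: dict[Term, set[Triple]] = {}
        self._by_o: dict[Term, set[Triple]] = {}
        for t in facts:
            self.add(t)

    # -- basic set interface ------------------------------------------------

    def __len__(self) -> int:
        return len(self._facts)

    def __contains__(self, t: Triple) -> bool:
        return t in self._facts

    def __iter__(self) -> Iterator[Triple]:
        return iter(self._facts)

    @property
    def facts(self) -> frozenset[Triple]:
        return frozenset(self._facts)

    def add(self, t: Triple) -> bool:
        """Add a fact; returns True if it was new."""
        if t in self._facts:
            return False
        self._facts.add(t)
        self._by_s.setdefault(t.subject, set()).add(t)
        self._by_p.setdefault(t.predicate, set()).add(t)
        self._by_o.setdefault(t.object, set()).add(t)
        return True

    def remove(self, t: Triple) -> None:
        self._facts.remove(t)
        for index, key in ((self._by_s, t.subject), (self._by_p, t.predicate), (self._by_o, t.object)):
            bucket = index[key]
            bucket.discard(t)
            if not bucket:
                del index[key]

    def update(self, triples: Iterable[Triple]) -> int:
        return sum(self.add(t) for t in triples)

    def copy(self) -> "TripleStore":
        return TripleStore(self._facts, dict(self.prefixes._map))

    def sorted_facts(self) -> list[Triple]:
        return sorted(self._facts, key=sort_key)

    # -- pattern matching ---------------------------------------------------

    def match(self, pattern: Pattern) -> list[Triple]:
        """All facts unifying with ``pattern``, sorted.

        Constants match exactly; variables match anything; a variable repeated
        within the pattern must bind to the same term in every position.
        """
        s, p, o = pattern
        candidates: set[Triple] | None = None
        for term, index in ((s, self._by_s), (p, self._by_p), (o, self._by_o)):
            if not term.is_var:
                bucket = index.get(term, set())
                candidates = bucket if candidates is None else candidates & bucket
        if candidates is None:
            candidates = self._facts
        out = [t for t in candidates if unify(pattern, t) is not None]
        out.sort(key=sort_key)
        return out


def unify(pattern: Pattern, fact: Triple) -> dict[str, Term] | None:
    """Binding map if ``fact`` matches ``pattern``, else None.

    Repeated variables must bind consistently; constants must equal the fact's
    term at that position.
    """
    binding: dict[str, Term] = {}
    for pat_term, fact_term in zip(pattern, fact):
        if pat_term.is_var:
            bound = binding.get(pat_term.value)
            if bound is None:
                binding[pat_term.value] = fact_term
            elif bound != fact_term:
                return None
        elif pat_term != fact_term:
            return None
    return binding


def substitute(pattern: Pattern, binding: Mapping[str, Term]) -> Pattern:
    """Apply a binding to a pattern; unbound variables stay in place."""
    return tuple(
        binding.get(t.value, t) if t.is_var else t for t in pattern
    )  # type: ignore[return-value]


def pattern_vars(pattern: Pattern) -> set[str]:
    return {t.value for t in pattern if t.is_var}
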