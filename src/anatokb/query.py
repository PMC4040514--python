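"""SELECT-style conjunctive queries over a (saturated) triple store.

The query language is the SPARQL SELECT / basic-graph-pattern subset:
``PREFIX`` headers, ``SELECT [DISTINCT] ?vars WHERE { pattern . pattern ... }``
with variables allowed in any position, including the predicate.  No OPTIONAL,
FILTER, UNION or property paths: inference at saturation time plays the role
property paths would otherwise play (querying ``InsertOn`` on the closed store
already sees insertions propagated up the partonomy).

Evaluation is a natural join of the pattern matches, computed by a nested-loop
join that greedily picks the cheapest (fewest-matches) pattern next.  Answer
tables are deterministic: rows sorted lexicographically, DISTINCT on by
default to mirror the store's set semantics.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable

from .model import Pattern, PrefixTable, Term, TripleStore, pattern_vars, substitute, unify
from .rules import ClosedStore

logger = logging.getLogger(__name__)


class QuerySyntaxError(ValueError):
    pass


@dataclass(frozen=True)
class Query:
    """Projected variables + conjunctive triple patterns."""

    projected: tuple[str, ...]
    patterns: tuple[Pattern, ...]
    distinct: bool = True

    def __post_init__(self) -> None:
        if not self.projected:
            raise QuerySyntaxError("no projected variables")
        if not self.patterns:
            raise QuerySyntaxError("no patterns")
        in_patterns: set[str] = set()
        for p in self.patterns:
            in_patterns |= pattern_vars(p)
        missing = [v for v in self.projected if v not in in_patterns]
        if missing:
            raise QuerySyntaxError(
                "projected variable(s) absent from all patterns: "
                + ", ".join("?" + v for v in missing)
            )


@dataclass
class AnswerTable:
    """Solution table: header of variable names, rows of ground terms."""

    header: tuple[str, ...]
    rows: list[tuple[Term, ...]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, name: str) -> list[Term]:
        i = self.header.index(name)
        return [row[i] for row in self.rows]

    def values(self, name: str) -> set[str]:
        return {t.value for t in self.column(name)}

    def to_tsv(self, prefixes: PrefixTable | None = None) -> str:
        """Tab-separated export with a header row; IRIs compacted if a prefix
        table is supplied."""

        def render(t: Term) -> str:
            if t.kind == "literal":
                return t.value
            return prefixes.compact(t.value) if prefixes is not None else t.value

        lines = ["\t".join("?" + v for v in self.header)]
        lines += ["\t".join(render(t) for t in row) for row in self.rows]
        return "\n".join(lines) + "\n"


# -- parsing ----------------------------------------------------------------

_PREFIX_RE = re.compile(r"PREFIX\s+([A-Za-z][\w.-]*)?:\s*<([^<>\s]*)>", re.IGNORECASE)
_SELECT_RE = re.compile(
    r"SELECT\s+(?P<distinct>DISTINCT\s+)?(?P<vars>(?:\?\w+\s*)+)WHERE\s*\{(?P<body>.*)\}",
    re.IGNORECASE | re.DOTALL,
)
_TERM_RE = re.compile(
    r"""\s*(?:
        (?P<var>\?\w+) |
        (?P<iri><[^<>\s]*>) |
        (?P<literal>"(?:[^"\\]|\\.)*") |
        (?P<qname>[A-Za-z][\w.-]*:[\w][\w.-]*|[A-Za-z][\w.-]*:[\w.-]*|a\b) |
        (?P<dot>\.)
    )""",
    re.VERBOSE,
)


def parse_query(text: str, prefixes: PrefixTable | None = None) -> Query:
    """Parse SELECT-subset query text into a :class:`Query`.

    PREFIX headers extend (and may shadow) the supplied/default prefix table;
    prefixed names expand exactly as the triple readers expand them.
    """
    from .model import iri, lit, var  # local to avoid cluttering module surface

    table = prefixes if prefixes is not None else PrefixTable()
    stripped = []
    for line in text.splitlines():
        # '#' comments; keep '#'s inside IRI brackets and quotes
        out, in_iri, in_str = [], False, False
        for ch in line:
            if ch == "<" and not in_str:
                in_iri = True
            elif ch == ">" and not in_str:
                in_iri = False
            elif ch == '"' and not in_iri:
                in_str = not in_str
            if ch == "#" and not in_iri and not in_str:
                break
            out.append(ch)
        stripped.append("".join(out))
    text = "\n".join(stripped)

    for m in _PREFIX_RE.finditer(text):
        table.bind(m.group(1) or "", m.group(2))
    text_wo_prefix = _PREFIX_RE.sub("", text)

    m = _SELECT_RE.search(text_wo_prefix)
    if m is None:
        raise QuerySyntaxError("expected SELECT [DISTINCT] ?vars WHERE { ... }")
    projected = tuple(v[1:] for v in m.group("vars").split())
    # set semantics of the store: DISTINCT is the default, the keyword is
    # accepted for SPARQL compatibility
    distinct = True

    terms: list[Term | None] = []  # None marks a dot separator
    body, pos = m.group("body"), 0
    while pos < len(body):
        if body[pos:].strip() == "":
            break
        tm = _TERM_RE.match(body, pos)
        if tm is None:
            raise QuerySyntaxError(f"cannot parse pattern text near {body[pos:pos + 30]!r}")
        kind = tm.lastgroup
        tok = tm.group(kind)  # type: ignore[index]
        if kind == "dot":
            terms.append(None)
        elif kind == "var":
            terms.append(var(tok[1:]))
        elif kind == "iri":
            terms.append(iri(tok[1:-1]))
        elif kind == "literal":
            terms.append(lit(tok[1:-1].replace('\\"', '"').replace("\\\\", "\\")))
        else:
            try:
                terms.append(iri(table.expand(tok)))
            except KeyError:
                raise QuerySyntaxError(f"unknown prefix in {tok!r}") from None
        pos = tm.end()

    patterns: list[Pattern] = []
    chunk: list[Term] = []
    for t in terms + [None]:
        if t is None:
            if not chunk:
                continue
            if len(chunk) != 3:
                raise QuerySyntaxError(f"pattern with {len(chunk)} terms (need 3)")
            patterns.append(tuple(chunk))  # type: ignore[arg-type]
            chunk = []
        else:
            chunk.append(t)

    return Query(projected, tuple(patterns), distinct)


# -- evaluation -------------------------------------------------------------


def _join(store: TripleStore, patterns: Iterable[Pattern]) -> Iterable[dict[str, Term]]:
    """Nested-loop natural join, greedily expanding the cheapest pattern next."""

    def rec(remaining: list[Pattern], binding: dict[str, Term]):
        if not remaining:
            yield binding
            return
        # cheapest first: fewest matches under the current binding
        costed = sorted(
            ((len(store.match(substitute(p, binding))), i) for i, p in enumerate(remaining)),
        )
        _, best = costed[0]
        pat = substitute(remaining[best], binding)
        rest = remaining[:best] + remaining[best + 1:]
        for fact in store.match(pat):
            ext = unify(pat, fact)
            if ext is None:  # pragma: no cover
                continue
            merged = dict(binding)
            merged.update(ext)
            yield from rec(rest, merged)

    yield from rec(list(patterns), {})


def evaluate(query: Query, store: TripleStore) -> AnswerTable:
    """All solutions of the query's basic graph pattern over ``store``.

    Deterministic: rows sorted lexicographically by term text.  Evaluating
    against a store that has not been saturated is allowed but logged as a
    warning, since entailed answers will be missing.
    """
    if not isinstance(store, ClosedStore):
        logger.warning("evaluating query against an unsaturated store; entailed answers may be missing")
    rows = [
        tuple(binding[v] for v in query.projected)
        for binding in _join(store, query.patterns)
    ]
    if query.distinct:
        rows = list(set(rows))
    rows.sort(key=lambda row: tuple((t.kind, t.value) for t in row))
    return AnswerTable(query.projected, rows)
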