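"""Readers and writers for N-Triples and a Turtle subset.

Both dialects are deliberately restricted to what the knowledge base needs:
one statement per line, IRIs and plain literals only — no blank nodes, no
collections, no language tags or datatypes, and no ``;``/``,`` abbreviation
sugar in Turtle.  The writers emit deterministic output (statements sorted by
subject, predicate, object) so that stores serialize reproducibly; rdflib is
used in the test suite as the independent grammar oracle for round-trips.

Parsers report document order and carry line numbers in their errors, and an
unknown prefix raises :class:`UnknownPrefixError` rather than a generic
syntax error — contracts a general-purpose RDF parser does not expose, which
is why these line-oriented readers are implemented here.
"""

from __future__ import annotations

import re

from .model import IRI, LITERAL, PrefixTable, Term, Triple, TripleStore, iri, lit

NTRIPLES = "ntriples"
TURTLE = "turtle-subset"
DIALECTS = (NTRIPLES, TURTLE)


class RdfParseError(ValueError):
    """Malformed statement; ``line`` is the 1-based source line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class UnknownPrefixError(RdfParseError):
    """A prefixed name used a prefix with no declaration."""

    def __init__(self, prefix: str, line: int):
        RdfParseError.__init__(self, f"unknown prefix {prefix!r}", line)
        self.prefix = prefix


_TOKEN = re.compile(
    r"""\s*(?:
        (?P<iri><[^<>\s]*>) |
        (?P<literal>"(?:[^"\\]|\\.)*") |
        (?P<qname>[A-Za-z][\w.-]*:[\w][\w.-]*|[A-Za-z][\w.-]*:) |
        (?P<dot>\.)
    )""",
    re.VERBOSE,
)


def _escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n").replace("\t", "\\t")


def _unescape(s: str) -> str:
    return (
        s.replace("\\t", "\t").replace("\\n", "\n").replace('\\"', '"').replace("\\\\", "\\")
    )


def _tokenize(line: str, lineno: int) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(line):
        if line[pos:].strip() == "":
            break
        m = _TOKEN.match(line, pos)
        if m is None:
            raise RdfParseError(f"cannot tokenize near {line[pos:pos + 20]!r}", lineno)
        kind = m.lastgroup
        tokens.append((kind, m.group(kind)))  # type: ignore[arg-type]
        pos = m.end()
    return tokens


def _term(kind: str, text: str, prefixes: PrefixTable, lineno: int, allow_qname: bool) -> Term:
    if kind == "iri":
        return iri(text[1:-1])
    if kind == "literal":
        return lit(_unescape(text[1:-1]))
    if kind == "qname":
        if not allow_qname:
            raise RdfParseError(f"prefixed name {text!r} not allowed in this dialect", lineno)
        try:
            return iri(prefixes.expand(text))
        except KeyError:
            raise UnknownPrefixError(text.partition(":")[0], lineno) from None
    raise RdfParseError(f"unexpected token {text!r}", lineno)


def _statement(tokens: list[tuple[str, str]], prefixes: PrefixTable, lineno: int, allow_qname: bool) -> Triple:
    if len(tokens) != 4 or tokens[3][0] != "dot":
        raise RdfParseError("expected 'subject predicate object .'", lineno)
    s, p, o = (_term(k, v, prefixes, lineno, allow_qname) for k, v in tokens[:3])
    if s.kind != IRI:
        raise RdfParseError("subject must be an IRI", lineno)
    if p.kind != IRI:
        raise RdfParseError("predicate must be an IRI", lineno)
    return Triple(s, p, o)


_PREFIX_DECL = re.compile(r"@prefix\s+([A-Za-z][\w.-]*)?:\s*<([^<>\s]*)>\s*\.\s*$")


def parse_rdf(text: str, dialect: str = NTRIPLES, prefixes: PrefixTable | None = None) -> list[Triple]:
    """Parse a document into its triples, in document order.

    ``dialect`` is ``"ntriples"`` (full IRIs only) or ``"turtle-subset"``
    (``@prefix`` declarations plus simple one-line statements with prefixed
    names allowed).  Prefixed names are expanded against the declarations seen
    so far, seeded from ``prefixes`` (the default table if omitted).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    table = prefixes if prefixes is not None else PrefixTable()
    out: list[Triple] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if dialect == TURTLE and line.startswith("@prefix"):
            m = _PREFIX_DECL.match(line)
            if m is None:
                raise RdfParseError("malformed @prefix declaration", lineno)
            table.bind(m.group(1) or "", m.group(2))
            continue
        tokens = _tokenize(line, lineno)
        out.append(_statement(tokens, table, lineno, allow_qname=(dialect == TURTLE)))
    return out


def parse_store(text: str, dialect: str = NTRIPLES) -> TripleStore:
    """Parse a document straight into a fresh :class:`TripleStore`.

    The store's prefix table starts from the defaults and absorbs any
    ``@prefix`` declarations in the document.
    """
    store = TripleStore()
    store.update(parse_rdf(text, dialect, prefixes=store.prefixes))
    return store


def _nt_term(t: Term) -> str:
    if t.kind == LITERAL:
        return f'"{_escape(t.value)}"'
    return f"<{t.value}>"


def _ttl_term(t: Term, prefixes: PrefixTable) -> str:
    if t.kind == LITERAL:
        return f'"{_escape(t.value)}"'
    compact = prefixes.compact(t.value)
    if compact != t.value and _TOKEN.fullmatch(compact) and ":" in compact:
        return compact
    return f"<{t.value}>"


def serialize_rdf(store: TripleStore, dialect: str = NTRIPLES) -> str:
    """Serialize a store deterministically (sorted by subject, predicate, object)."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    lines: list[str] = []
    if dialect == TURTLE:
        for prefix, ns in store.prefixes.items():
            lines.append(f"@prefix {prefix}: <{ns}> .")
        if lines:
            lines.append("")
        render = lambda t: _ttl_term(t, store.prefixes)  # noqa: E731
    else:
        render = _nt_term
    for t in store.sorted_facts():
        lines.append(f"{render(t.subject)} {render(t.predicate)} {render(t.object)} .")
    return "\n".join(lines) + "\n"
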