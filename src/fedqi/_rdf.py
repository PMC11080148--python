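"""Minimal RDF triple store with Turtle and N-Triples round-tripping.

The FAIRified patient graphs used here are star-shaped, ground (no blank
nodes) and modest in size, so a plain set of triples with subject/predicate
indexes is the right container.  Turtle output is restricted to the
one-statement-per-line profile (``@prefix`` declarations followed by
``s p o .`` statements); the parser additionally accepts ``;`` / ``,``
predicate and object lists so that hand-edited files load fine.  Every
document this module writes is valid Turtle / N-Triples per the W3C
grammars.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Iterator, Optional, Union

# --- namespaces -----------------------------------------------------------

XSD = "http://www.w3.org/2001/XMLSchema#"
RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS = "http://www.w3.org/2000/01/rdf-schema#"

XSD_STRING = XSD + "string"
XSD_DATE = XSD + "date"
XSD_BOOLEAN = XSD + "boolean"
XSD_INTEGER = XSD + "integer"
XSD_DECIMAL = XSD + "decimal"
RDF_TYPE = RDF + "type"
RDFS_LABEL = RDFS + "label"

DEFAULT_PREFIXES = {
    "rdf": RDF,
    "rdfs": RDFS,
    "xsd": XSD,
}


class RdfError(ValueError):
    """Malformed RDF document or term."""


@dataclass(frozen=True)
class IRI:
    value: str

    def __post_init__(self) -> None:
        if "://" not in self.value and not self.value.startswith("urn:"):
            raise RdfError(f"IRI must be absolute: {self.value!r}")

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.value


@dataclass(frozen=True)
class Literal:
    """Typed literal; ``lexical`` is the canonical lexical form."""

    lexical: str
    datatype: str = XSD_STRING

    def to_python(self) -> Union[str, int, float, bool, date]:
        if self.datatype == XSD_BOOLEAN:
            return self.lexical == "true"
        if self.datatype == XSD_INTEGER:
            return int(self.lexical)
        if self.datatype == XSD_DECIMAL:
            return float(self.lexical)
        if self.datatype == XSD_DATE:
            return date.fromisoformat(self.lexical)
        return self.lexical

    @staticmethod
    def from_python(value: Union[str, int, float, bool, date]) -> "Literal":
        if isinstance(value, bool):
            return Literal("true" if value else "false", XSD_BOOLEAN)
        if isinstance(value, int):
            return Literal(str(value), XSD_INTEGER)
        if isinstance(value, float):
            return Literal(repr(value), XSD_DECIMAL)
        if isinstance(value, date):
            return Literal(value.isoformat(), XSD_DATE)
        return Literal(str(value), XSD_STRING)


Term = Union[IRI, Literal]
Triple = tuple[IRI, IRI, Term]


class Graph:
    """A set of ground triples with (s, p) and (p,) lookup indexes."""

    def __init__(self, triples: Optional[Iterable[Triple]] = None) -> None:
        self._triples: set[Triple] = set()
        self._sp: dict[tuple[IRI, IRI], list[Term]] = {}
        self._p: dict[IRI, list[tuple[IRI, Term]]] = {}
        if triples:
            for t in triples:
                self.add(*t)

    def add(self, s: IRI, p: IRI, o: Term) -> None:
        t = (s, p, o)
        if t in self._triples:
            return
        self._triples.add(t)
        self._sp.setdefault((s, p), []).append(o)
        self._p.setdefault(p, []).append((s, o))

    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self._triples)

    def __contains__(self, t: Triple) -> bool:
        return t in self._triples

    def triples(
        self,
        s: Optional[IRI] = None,
        p: Optional[IRI] = None,
        o: Optional[Term] = None,
    ) -> Iterator[Triple]:
        """Pattern match; ``None`` is a wildcard.  Uses indexes when possible."""
        if s is not None and p is not None:
            for obj in self._sp.get((s, p), ()):
                if o is None or obj == o:
                    yield (s, p, obj)
        elif p is not None:
            for subj, obj in self._p.get(p, ()):
                if (s is None or subj == s) and (o is None or obj == o):
                    yield (subj, p, obj)
        else:
            for t in self._triples:
                if (
                    (s is None or t[0] == s)
                    and (p is None or t[1] == p)
                    and (o is None or t[2] == o)
                ):
                    yield t

    def objects(self, s: IRI, p: IRI) -> list[Term]:
        return list(self._sp.get((s, p), ()))

    def object(self, s: IRI, p: IRI) -> Optional[Term]:
        objs = self._sp.get((s, p))
        return objs[0] if objs else None

    def subjects(self, p: IRI, o: Optional[Term] = None) -> list[IRI]:
        return [subj for subj, obj in self._p.get(p, ()) if o is None or obj == o]

    # --- serialization ----------------------------------------------------

    def serialize(
        self,
        format: str = "turtle",
        prefixes: Optional[dict[str, str]] = None,
    ) -> str:
        if format in ("turtle", "ttl"):
            return _write_turtle(self, {**DEFAULT_PREFIXES, **(prefixes or {})})
        if format in ("ntriples", "nt"):
            return _write_ntriples(self)
        raise RdfError(f"unknown RDF serialization format: {format!r}")

    @classmethod
    def parse(cls, text: str, format: str = "turtle") -> "Graph":
        if format in ("turtle", "ttl"):
            return _parse_turtle(text)
        if format in ("ntriples", "nt"):
            return _parse_ntriples(text)
        raise RdfError(f"unknown RDF serialization format: {format!r}")


def isomorphic(a: Graph, b: Graph) -> bool:
    """Graphs here are ground (no blank nodes): isomorphism is set equality."""
    return set(a) == set(b)


# --- shared lexical helpers -----------------------------------------------

_ESCAPES = {"\\": "\\\\", '"': '\\"', "\n": "\\n", "\r": "\\r", "\t": "\\t"}
_UNESCAPES = {"\\": "\\", '"': '"', "n": "\n", "r": "\r", "t": "\t"}


def _escape(s: str) -> str:
    return "".join(_ESCAPES.get(c, c) for c in s)


def _unescape(s: str) -> str:
    out, i = [], 0
    while i < len(s):
        c = s[i]
        if c == "\\":
            if i + 1 >= len(s):
                raise RdfError("dangling escape in literal")
            nxt = s[i + 1]
            if nxt == "u":
                out.append(chr(int(s[i + 2 : i + 6], 16)))
                i += 6
                continue
            if nxt not in _UNESCAPES:
                raise RdfError(f"unknown escape \\{nxt}")
            out.append(_UNESCAPES[nxt])
            i += 2
        else:
            out.append(c)
            i += 1
    return "".join(out)


def _nt_term(t: Term) -> str:
    if isinstance(t, IRI):
        return f"<{t.value}>"
    if t.datatype == XSD_STRING:
        return f'"{_escape(t.lexical)}"'
    return f'"{_escape(t.lexical)}"^^<{t.datatype}>'


def _write_ntriples(g: Graph) -> str:
    lines = sorted(f"{_nt_term(s)} {_nt_term(p)} {_nt_term(o)} ." for s, p, o in g)
    return "\n".join(lines) + ("\n" if lines else "")


_PN_LOCAL = re.compile(r"^[A-Za-z0-9_][A-Za-z0-9_\-]*$")


def _write_turtle(g: Graph, prefixes: dict[str, str]) -> str:
    # longest-namespace-first so nested namespaces shorten correctly
    ordered = sorted(prefixes.items(), key=lambda kv: -len(kv[1]))

    def shorten(t: Term) -> str:
        if isinstance(t, Literal):
            if t.datatype == XSD_STRING:
                return f'"{_escape(t.lexical)}"'
            dt = shorten(IRI(t.datatype))
            return f'"{_escape(t.lexical)}"^^{dt}'
        if t.value == RDF_TYPE:
            return "a"
        for pfx, ns in ordered:
            if t.value.startswith(ns) and _PN_LOCAL.match(t.value[len(ns) :] or "-"):
                return f"{pfx}:{t.value[len(ns):]}"
        return f"<{t.value}>"

    used = {pfx: ns for pfx, ns in prefixes.items()}
    header = [f"@prefix {p}: <{ns}> ." for p, ns in sorted(used.items())]
    body = sorted(f"{shorten(s)} {shorten(p)} {shorten(o)} ." for s, p, o in g)
    return "\n".join(header + [""] + body) + "\n"


# --- N-Triples parser -----------------------------------------------------

_NT_LINE = re.compile(
    r"^\s*<(?P<s>[^>]*)>\s+<(?P<p>[^>]*)>\s+"
    r"(?:<(?P<oi>[^>]*)>|\"(?P<ol>(?:[^\"\\]|\\.)*)\"(?:\^\^<(?P<dt>[^>]*)>)?)"
    r"\s*\.\s*$"
)


def _parse_ntriples(text: str) -> Graph:
    g = Graph()
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        m = _NT_LINE.match(line)
        if not m:
            raise RdfError(f"malformed N-Triples statement at line {lineno}")
        s, p = IRI(m["s"]), IRI(m["p"])
        if m["oi"] is not None:
            o: Term = IRI(m["oi"])
        else:
            o = Literal(_unescape(m["ol"]), m["dt"] or XSD_STRING)
        g.add(s, p, o)
    return g


# --- Turtle parser --------------------------------------------------------

_TTL_TOKEN = re.compile(
    r"""
    (?P<ws>\s+|\#[^\n]*)
  | (?P<prefix>@prefix\b|PREFIX\b)
  | (?P<iriref><[^<>\s]*>)
  | (?P<literal>"(?:[^"\\]|\\.)*")
  | (?P<dtmark>\^\^)
  | (?P<punct>[.;,])
  | (?P<a>\ba\b)
  | (?P<pname>[A-Za-z][\w\-]*)?:(?P<local>[\w\-.]*)
    """,
    re.VERBOSE,
)


def _parse_turtle(text: str) -> Graph:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TTL_TOKEN.match(text, pos)
        if not m:
            raise RdfError(f"Turtle syntax error at offset {pos}: {text[pos:pos+20]!r}")
        pos = m.end()
        kind = m.lastgroup
        if kind == "ws":
            continue
        if kind == "local":  # pname group matched (possibly empty prefix)
            tokens.append(("pname", m.group(0), m.start()))
        else:
            tokens.append((kind, m.group(0), m.start()))

    g = Graph()
    prefixes: dict[str, str] = {}
    i = 0

    def expect(kind: str) -> tuple[str, str, int]:
        nonlocal i
        if i >= len(tokens) or tokens[i][0] != kind:
            at = tokens[i][2] if i < len(tokens) else len(text)
            raise RdfError(f"Turtle syntax error at offset {at}")
        tok = tokens[i]
        i += 1
        return tok

    def term() -> Term:
        nonlocal i
        if i >= len(tokens):
            raise RdfError(f"unexpected end of document at offset {len(text)}")
        kind, val, at = tokens[i]
        if kind == "iriref":
            i += 1
            return IRI(val[1:-1])
        if kind == "a":
            i += 1
            return IRI(RDF_TYPE)
        if kind == "pname":
            i += 1
            pfx, _, local = val.partition(":")
            if pfx not in prefixes:
                raise RdfError(f"undeclared prefix {pfx!r} at offset {at}")
            return IRI(prefixes[pfx] + local)
        if kind == "literal":
            i += 1
            lex = _unescape(val[1:-1])
            if i < len(tokens) and tokens[i][0] == "dtmark":
                i += 1
                dt = term()
                if not isinstance(dt, IRI):
                    raise RdfError("literal datatype must be an IRI")
                return Literal(lex, dt.value)
            return Literal(lex)
        raise RdfError(f"unexpected token {val!r} at offset {at}")

    while i < len(tokens):
        if tokens[i][0] == "prefix":
            i += 1
            _, pname, _ = expect("pname")
            _, iriref, _ = expect("iriref")
            prefixes[pname.partition(":")[0]] = iriref[1:-1]
            if i < len(tokens) and tokens[i][1] == ".":
                i += 1
            continue
        s = term()
        if not isinstance(s, IRI):
            raise RdfError("triple subject must be an IRI")
        while True:  # predicate lists separated by ';'
            p = term()
            if not isinstance(p, IRI):
                raise RdfError("triple predicate must be an IRI")
            while True:  # object lists separated by ','
                g.add(s, p, term())
                if i < len(tokens) and tokens[i][1] == ",":
                    i += 1
                    continue
                break
            if i < len(tokens) and tokens[i][1] == ";":
                i += 1
                if i < len(tokens) and tokens[i][1] == ".":
                    break
                continue
            break
        _, punct, at = tokens[i] if i < len(tokens) else ("", "", len(text))
        if punct != ".":
            raise RdfError(f"expected '.' at offset {at}")
        i += 1
    return g
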