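"""SPARQL 1.1 SELECT subset evaluator for in-process FAIR stations.

Supports exactly the fragment the shipped cohort-retrieval queries need:
``PREFIX`` declarations, ``SELECT`` with explicit variables or ``*``, basic
graph patterns, ``OPTIONAL`` groups and ``FILTER`` expressions (comparisons,
``&&``/``||``/``!``, parentheses).  Evaluation is a nested-loop join driven
by the graph's (subject, predicate) indexes, which is linear in cohort size
for the star-shaped patient graphs produced by triplification.

Queries referencing predicates absent from a graph simply bind nothing and
yield zero rows; only syntactically malformed queries raise, with the
character offset of the failure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Union

from ._rdf import RDF_TYPE, XSD_BOOLEAN, XSD_DECIMAL, XSD_INTEGER, Graph, IRI, Literal, Term


class SparqlParseError(ValueError):
    """Syntactically invalid query; carries the offending character offset."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Variable:
    name: str


PatternTerm = Union[IRI, Literal, Variable]
TriplePattern = tuple[PatternTerm, PatternTerm, PatternTerm]
Binding = dict[str, Term]


# --- expression AST -------------------------------------------------------

@dataclass(frozen=True)
class Comparison:
    op: str
    left: PatternTerm
    right: PatternTerm


@dataclass(frozen=True)
class BoolOp:
    op: str  # "&&" | "||" | "!"
    operands: tuple


@dataclass
class GroupPattern:
    triples: list[TriplePattern] = field(default_factory=list)
    optionals: list["GroupPattern"] = field(default_factory=list)
    filters: list[Union[Comparison, BoolOp]] = field(default_factory=list)


@dataclass
class SelectQuery:
    variables: Optional[list[str]]  # None means SELECT *
    pattern: GroupPattern


@dataclass
class QueryResult:
    """Tabular SELECT result: one tuple per solution, ``None`` where unbound."""

    variable_names: list[str]
    rows: list[tuple]

    def __len__(self) -> int:
        return len(self.rows)

    def to_dicts(self) -> list[dict]:
        return [dict(zip(self.variable_names, row)) for row in self.rows]


# --- tokenizer ------------------------------------------------------------

_TOKEN = re.compile(
    r"""
    (?P<ws>\s+|\#[^\n]*)
  | (?P<keyword>(?i:PREFIX|SELECT|WHERE|OPTIONAL|FILTER)\b)
  | (?P<var>\?[A-Za-z_][\w]*)
  | (?P<iriref><[^<>\s]*>)
  | (?P<string>"(?:[^"\\]|\\.)*")
  | (?P<number>[+-]?\d+(?:\.\d+)?)
  | (?P<bool>\b(?:true|false)\b)
  | (?P<a>\ba\b)
  | (?P<pname>[A-Za-z][\w\-]*)?:(?P<local>[\w\-.]*)
  | (?P<op>&&|\|\||!=|<=|>=|=|<|>|!)
  | (?P<punct>[{}().,;*^])
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise SparqlParseError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        if kind != "ws":
            if kind == "local":
                kind = "pname"
            tokens.append((kind, m.group(0), m.start()))
        pos = m.end()
    return tokens


# --- parser ---------------------------------------------------------------

class _Parser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0
        self.prefixes: dict[str, str] = {}

    def _peek(self) -> tuple[str, str, int]:
        if self.i < len(self.tokens):
            return self.tokens[self.i]
        return ("eof", "", len(self.text))

    def _next(self) -> tuple[str, str, int]:
        tok = self._peek()
        self.i += 1
        return tok

    def _expect(self, value: str) -> None:
        kind, val, at = self._next()
        if val.upper() != value.upper():
            raise SparqlParseError(f"expected {value!r}, got {val!r}", at)

    def parse(self) -> SelectQuery:
        while self._peek()[1].upper() == "PREFIX":
            self._next()
            kind, val, at = self._next()
            if kind != "pname":
                raise SparqlParseError("expected prefix name", at)
            pfx = val.partition(":")[0]
            kind, iri, at = self._next()
            if kind != "iriref":
                raise SparqlParseError("expected IRI after prefix name", at)
            self.prefixes[pfx] = iri[1:-1]
        self._expect("SELECT")
        variables: Optional[list[str]] = None
        if self._peek()[1] == "*":
            self._next()
        else:
            variables = []
            while self._peek()[0] == "var":
                variables.append(self._next()[1][1:])
            if not variables:
                raise SparqlParseError("SELECT needs variables or *", self._peek()[2])
        if self._peek()[1].upper() == "WHERE":
            self._next()
        pattern = self._group()
        kind, val, at = self._peek()
        if kind != "eof":
            raise SparqlParseError(f"trailing content {val!r}", at)
        return SelectQuery(variables, pattern)

    def _group(self) -> GroupPattern:
        self._expect("{")
        gp = GroupPattern()
        while True:
            kind, val, at = self._peek()
            if val == "}":
                self._next()
                return gp
            if kind == "eof":
                raise SparqlParseError("unterminated group pattern", at)
            if val.upper() == "OPTIONAL":
                self._next()
                gp.optionals.append(self._group())
            elif val.upper() == "FILTER":
                self._next()
                self._expect("(")
                gp.filters.append(self._expr())
                self._expect(")")
            else:
                s = self._term()
                p = self._term()
                o = self._term()
                gp.triples.append((s, p, o))
                if self._peek()[1] == ".":
                    self._next()

    def _term(self) -> PatternTerm:
        kind, val, at = self._next()
        if kind == "var":
            return Variable(val[1:])
        if kind == "iriref":
            return IRI(val[1:-1])
        if kind == "a":
            return IRI(RDF_TYPE)
        if kind == "pname":
            pfx, _, local = val.partition(":")
            if pfx not in self.prefixes:
                raise SparqlParseError(f"undeclared prefix {pfx!r}", at)
            return IRI(self.prefixes[pfx] + local)
        if kind == "string":
            lex = val[1:-1].replace('\\"', '"').replace("\\\\", "\\")
            if self._peek()[1] == "^":  # ^^datatype
                self._next()
                self._expect("^")
                dt = self._term()
                if not isinstance(dt, IRI):
                    raise SparqlParseError("datatype must be an IRI", at)
                return Literal(lex, dt.value)
            return Literal(lex)
        if kind == "number":
            dt = XSD_DECIMAL if "." in val else XSD_INTEGER
            return Literal(val, dt)
        if kind == "bool":
            return Literal(val, XSD_BOOLEAN)
        raise SparqlParseError(f"unexpected token {val!r}", at)

    # precedence: || < && < ! < comparison
    def _expr(self):
        left = self._and_expr()
        while self._peek()[1] == "||":
            self._next()
            left = BoolOp("||", (left, self._and_expr()))
        return left

    def _and_expr(self):
        left = self._unary_expr()
        while self._peek()[1] == "&&":
            self._next()
            left = BoolOp("&&", (left, self._unary_expr()))
        return left

    def _unary_expr(self):
        if self._peek()[1] == "!":
            self._next()
            return BoolOp("!", (self._unary_expr(),))
        if self._peek()[1] == "(":
            self._next()
            inner = self._expr()
            self._expect(")")
            return inner
        left = self._term()
        kind, op, at = self._peek()
        if op in ("=", "!=", "<", "<=", ">", ">="):
            self._next()
            return Comparison(op, left, self._term())
        raise SparqlParseError("expected comparison operator", at)


def parse_query(text: str) -> SelectQuery:
    return _Parser(text).parse()


# --- evaluation -----------------------------------------------------------

def _match_pattern(g: Graph, pattern: TriplePattern, binding: Binding) -> list[Binding]:
    def resolve(t: PatternTerm) -> Optional[Term]:
        if isinstance(t, Variable):
            return binding.get(t.name)
        return t

    s, p, o = (resolve(t) for t in pattern)
    if isinstance(s, Literal):
        return []
    out = []
    for ts, tp, to in g.triples(s, p if isinstance(p, IRI) else None, o):
        if p is not None and not isinstance(p, IRI) and tp != p:
            continue
        new = dict(binding)
        ok = True
        for var, val in zip(pattern, (ts, tp, to)):
            if isinstance(var, Variable):
                if var.name in new and new[var.name] != val:
                    ok = False
                    break
                new[var.name] = val
        if ok:
            out.append(new)
    return out


def _eval_bgp(g: Graph, patterns: list[TriplePattern], seeds: list[Binding]) -> list[Binding]:
    solutions = seeds
    for pattern in patterns:
        solutions = [b2 for b in solutions for b2 in _match_pattern(g, pattern, b)]
        if not solutions:
            break
    return solutions


def _value(term: Optional[Term]):
    if term is None:
        raise ValueError("unbound variable in FILTER")
    if isinstance(term, IRI):
        return term
    return term.to_python()


def _eval_expr(expr, binding: Binding) -> bool:
    if isinstance(expr, BoolOp):
        if expr.op == "!":
            return not _eval_expr(expr.operands[0], binding)
        vals = (_eval_expr(e, binding) for e in expr.operands)
        return all(vals) if expr.op == "&&" else any(vals)
    left, right = expr.left, expr.right
    lv = _value(binding.get(left.name)) if isinstance(left, Variable) else _value(left)
    rv = _value(binding.get(right.name)) if isinstance(right, Variable) else _value(right)
    if isinstance(lv, IRI) or isinstance(rv, IRI):
        if expr.op == "=":
            return lv == rv
        if expr.op == "!=":
            return lv != rv
        raise ValueError("ordering comparison on IRIs")
    if isinstance(lv, bool) != isinstance(rv, bool):
        raise ValueError("type mismatch in comparison")
    if isinstance(lv, date) != isinstance(rv, date):
        raise ValueError("type mismatch in comparison")
    if expr.op == "=":
        return lv == rv
    if expr.op == "!=":
        return lv != rv
    if expr.op == "<":
        return lv < rv
    if expr.op == "<=":
        return lv <= rv
    if expr.op == ">":
        return lv > rv
    return lv >= rv


def _eval_group(g: Graph, gp: GroupPattern, seeds: list[Binding]) -> list[Binding]:
    solutions = _eval_bgp(g, gp.triples, seeds)
    for opt in gp.optionals:
        joined: list[Binding] = []
        for b in solutions:
            extended = _eval_group(g, opt, [b])
            joined.extend(extended if extended else [b])
        solutions = joined
    for f in gp.filters:
        kept = []
        for b in solutions:
            try:
                if _eval_expr(f, b):
                    kept.append(b)
            except (ValueError, TypeError):
                pass  # SPARQL: expression error -> solution filtered out
        solutions = kept
    return solutions


def _collect_vars(gp: GroupPattern, acc: list[str]) -> list[str]:
    for pattern in gp.triples:
        for t in pattern:
            if isinstance(t, Variable) and t.name not in acc:
                acc.append(t.name)
    for opt in gp.optionals:
        _collect_vars(opt, acc)
    return acc


def evaluate(graph: Graph, query: Union[str, SelectQuery]) -> QueryResult:
    """Run a SELECT query against a graph and return the solution table."""
    q = parse_query(query) if isinstance(query, str) else query
    names = q.variables if q.variables is not None else _collect_vars(q.pattern, [])
    solutions = _eval_group(graph, q.pattern, [{}])
    rows = [tuple(b.get(n) for n in names) for b in solutions]
    return QueryResult(list(names), rows)
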