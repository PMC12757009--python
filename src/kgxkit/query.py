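"""Query expressions over node attributes.

``fetch_nodes`` and ``filter_nodes`` accept an explicit expression tree built
from three leaf forms and the usual boolean connectives:

* ``Equals(attribute, value)`` — the cell equals a scalar value. A
  multi-valued cell never satisfies ``Equals``; use ``InList``.
* ``Matches(attribute, pattern)`` — regular-expression search against the
  cell (any element, for a multi-valued cell).
* ``InList(value, attribute)`` — the multi-valued cell contains ``value``;
  a single-valued cell is treated as a one-element collection.

An attribute absent from the table (or empty for the row) makes a leaf
evaluate false — never an error. The CLI accepts a small textual syntax for
the same trees, e.g.::

    in_taxon_label == "Homo sapiens" and "biolink:Gene" in category
    id =~ "^HP:" or not (name == "unused")

parsed by :func:`parse_expr`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

from .kg_model import is_missing


class QueryError(ValueError):
    """A query expression is malformed (bad regex, unparsable text)."""


class QuerySyntaxError(QueryError):
    """Parse failure; carries the offending position for a caret message."""

    def __init__(self, message: str, text: str, pos: int):
        self.pos = pos
        caret = " " * pos + "^"
        super().__init__(f"{message}\n  {text}\n  {caret}")


class QueryExpr:
    """Base class; subclasses implement ``evaluate(row) -> bool``."""

    def evaluate(self, row: Mapping) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError

    def __and__(self, other: "QueryExpr") -> "And":
        return And(self, other)

    def __or__(self, other: "QueryExpr") -> "Or":
        return Or(self, other)

    def __invert__(self) -> "Not":
        return Not(self)


@dataclass(frozen=True)
class Equals(QueryExpr):
    attribute: str
    value: object

    def evaluate(self, row: Mapping) -> bool:
        cell = row.get(self.attribute)
        if is_missing(cell) or isinstance(cell, (list, tuple)):
            return False
        if isinstance(cell, bool) or isinstance(self.value, bool):
            return cell is self.value
        return cell == self.value


@dataclass(frozen=True)
class Matches(QueryExpr):
    attribute: str
    pattern: str

    def __post_init__(self):
        try:
            object.__setattr__(self, "_compiled", re.compile(self.pattern))
        except re.error as exc:
            raise QueryError(f"invalid regular expression {self.pattern!r}: {exc}")

    def evaluate(self, row: Mapping) -> bool:
        cell = row.get(self.attribute)
        if is_missing(cell):
            return False
        values = cell if isinstance(cell, (list, tuple)) else [cell]
        return any(self._compiled.search(str(v)) for v in values)


@dataclass(frozen=True)
class InList(QueryExpr):
    """value ∈ multi-valued attribute cell (scalar cells act as singletons)."""

    value: object
    attribute: str

    def evaluate(self, row: Mapping) -> bool:
        cell = row.get(self.attribute)
        if is_missing(cell):
            return False
        values = cell if isinstance(cell, (list, tuple)) else [cell]
        return any(v == self.value for v in values)


class And(QueryExpr):
    def __init__(self, *clauses: QueryExpr):
        self.clauses = tuple(clauses)

    def evaluate(self, row: Mapping) -> bool:
        return all(c.evaluate(row) for c in self.clauses)

    def __repr__(self):
        return f"And{self.clauses!r}"


class Or(QueryExpr):
    def __init__(self, *clauses: QueryExpr):
        self.clauses = tuple(clauses)

    def evaluate(self, row: Mapping) -> bool:
        return any(c.evaluate(row) for c in self.clauses)

    def __repr__(self):
        return f"Or{self.clauses!r}"


@dataclass(frozen=True)
class Not(QueryExpr):
    clause: QueryExpr

    def evaluate(self, row: Mapping) -> bool:
        return not self.clause.evaluate(row)


# ---------------------------------------------------------------------------
# Textual syntax
#
#   expr     := or
#   or       := and ("or" and)*
#   and      := unary ("and" unary)*
#   unary    := "not" unary | "(" expr ")" | comparison
#   compare  := IDENT "==" literal
#             | IDENT "=~" STRING
#             | literal "in" IDENT
#   literal  := STRING | NUMBER | "true" | "false"
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<op>==|=~|\(|\))
  | (?P<string>"(?:\\.|[^"\\])*")
  | (?P<number>-?\d+(?:\.\d+)?)
  | (?P<ident>[A-Za-z_][A-Za-z0-9_:.]*)
    """,
    re.VERBOSE,
)

_KEYWORDS = {"and", "or", "not", "in", "true", "false"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise QuerySyntaxError(f"unexpected character {text[pos]!r}", text, pos)
        kind = m.lastgroup
        value = m.group()
        if kind != "ws":
            if kind == "ident" and value in _KEYWORDS:
                kind = value
            tokens.append((kind, value, pos))
        pos = m.end()
    tokens.append(("end", "", len(text)))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def take(self, kind=None):
        tok = self.tokens[self.i]
        if kind is not None and tok[0] != kind:
            raise QuerySyntaxError(
                f"expected {kind}, found {tok[1] or 'end of input'!r}",
                self.text,
                tok[2],
            )
        self.i += 1
        return tok

    def parse(self) -> QueryExpr:
        expr = self.or_expr()
        tok = self.peek()
        if tok[0] != "end":
            raise QuerySyntaxError(f"unexpected {tok[1]!r}", self.text, tok[2])
        return expr

    def or_expr(self) -> QueryExpr:
        clauses = [self.and_expr()]
        while self.peek()[0] == "or":
            self.take()
            clauses.append(self.and_expr())
        return clauses[0] if len(clauses) == 1 else Or(*clauses)

    def and_expr(self) -> QueryExpr:
        clauses = [self.unary()]
        while self.peek()[0] == "and":
            self.take()
            clauses.append(self.unary())
        return clauses[0] if len(clauses) == 1 else And(*clauses)

    def unary(self) -> QueryExpr:
        tok = self.peek()
        if tok[0] == "not":
            self.take()
            return Not(self.unary())
        if tok[0] == "op" and tok[1] == "(":
            self.take()
            expr = self.or_expr()
            closing = self.take("op")
            if closing[1] != ")":
                raise QuerySyntaxError("expected ')'", self.text, closing[2])
            return expr
        return self.comparison()

    def literal(self):
        tok = self.take()
        kind, value, pos = tok
        if kind == "string":
            return _unquote(value)
        if kind == "number":
            return float(value) if "." in value else int(value)
        if kind == "true":
            return True
        if kind == "false":
            return False
        raise QuerySyntaxError(
            f"expected a literal, found {value or 'end of input'!r}", self.text, pos
        )

    def comparison(self) -> QueryExpr:
        tok = self.peek()
        if tok[0] == "ident":
            attr = self.take()[1]
            op = self.take()
            if op[0] == "op" and op[1] == "==":
                return Equals(attr, self.literal())
            if op[0] == "op" and op[1] == "=~":
                pat = self.take("string")
                try:
                    return Matches(attr, _unquote(pat[1]))
                except QueryError as exc:
                    raise QuerySyntaxError(str(exc), self.text, pat[2])
            raise QuerySyntaxError(
                f"expected '==', '=~' after attribute {attr!r}", self.text, op[2]
            )
        value = self.literal()
        kw = self.take()
        if kw[0] != "in":
            raise QuerySyntaxError("expected 'in' after literal", self.text, kw[2])
        attr = self.take("ident")
        return InList(value, attr[1])


def _unquote(s: str) -> str:
    body = s[1:-1]
    return re.sub(r"\\(.)", lambda m: {"n": "\n", "t": "\t"}.get(m.group(1), m.group(1)), body)


def parse_expr(text: str) -> QueryExpr:
    """Parse the textual query syntax into a :class:`QueryExpr` tree.

    Raises :class:`QuerySyntaxError` (with a caret-position message) on
    malformed input.
    """
    return _Parser(text).parse()
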