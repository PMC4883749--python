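"""Boolean rule expressions.

The rule grammar is deliberately small: identifiers, the literals ``0``/``1``,
``NOT``, ``AND``, ``OR`` and parentheses.  ``NOT`` binds tightest, then
``AND``, then ``OR``, so ``A OR B AND NOT C`` parses as ``A OR (B AND (NOT C))``.
Operator keywords are case-insensitive; identifiers are case-sensitive and may
contain letters, digits and underscores.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping


class ExpressionError(ValueError):
    """Raised for malformed expressions or references to unknown nodes."""


# --- AST ------------------------------------------------------------------


@dataclass(frozen=True)
class Var:
    name: str

    def evaluate(self, state: Mapping[str, int]) -> int:
        try:
            return 1 if state[self.name] else 0
        except KeyError:
            raise ExpressionError(f"unknown node {self.name!r} in expression")

    def variables(self) -> frozenset[str]:
        return frozenset({self.name})

    def unparse(self) -> str:
        return self.name


@dataclass(frozen=True)
class Const:
    value: int

    def evaluate(self, state: Mapping[str, int]) -> int:
        return self.value

    def variables(self) -> frozenset[str]:
        return frozenset()

    def unparse(self) -> str:
        return str(self.value)


@dataclass(frozen=True)
class Not:
    operand: "Node"

    def evaluate(self, state: Mapping[str, int]) -> int:
        return 1 - self.operand.evaluate(state)

    def variables(self) -> frozenset[str]:
        return self.operand.variables()

    def unparse(self) -> str:
        inner = self.operand.unparse()
        if isinstance(self.operand, (And, Or)):
            inner = f"({inner})"
        return f"NOT {inner}"


@dataclass(frozen=True)
class And:
    left: "Node"
    right: "Node"

    def evaluate(self, state: Mapping[str, int]) -> int:
        return self.left.evaluate(state) & self.right.evaluate(state)

    def variables(self) -> frozenset[str]:
        return self.left.variables() | self.right.variables()

    def unparse(self) -> str:
        parts = []
        for side in (self.left, self.right):
            text = side.unparse()
            if isinstance(side, Or):
                text = f"({text})"
            parts.append(text)
        return " AND ".join(parts)


@dataclass(frozen=True)
class Or:
    left: "Node"
    right: "Node"

    def evaluate(self, state: Mapping[str, int]) -> int:
        return self.left.evaluate(state) | self.right.evaluate(state)

    def variables(self) -> frozenset[str]:
        return self.left.variables() | self.right.variables()

    def unparse(self) -> str:
        return f"{self.left.unparse()} OR {self.right.unparse()}"


Node = Var | Const | Not | And | Or


# --- parser ---------------------------------------------------------------

_TOKEN = re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<word>[A-Za-z_][A-Za-z0-9_]*)|(?P<const>[01]))")


def _tokenize(text: str) -> Iterator[tuple[str, str]]:
    pos = 0
    while pos < len(text):
        match = _TOKEN.match(text, pos)
        if match is None:
            if text[pos:].strip():
                raise ExpressionError(f"unexpected character {text[pos:].strip()[0]!r}")
            break
        pos = match.end()
        if match.lastgroup == "word":
            word = match.group("word")
            upper = word.upper()
            if upper in ("AND", "OR", "NOT"):
                yield upper, word
            elif upper == "TRUE":
                yield "CONST", "1"
            elif upper == "FALSE":
                yield "CONST", "0"
            else:
                yield "VAR", word
        elif match.lastgroup == "const":
            yield "CONST", match.group("const")
        elif match.lastgroup == "lpar":
            yield "(", "("
        else:
            yield ")", ")"
    yield "END", ""


class _Parser:
    def __init__(self, text: str):
        self.tokens = list(_tokenize(text))
        self.pos = 0

    def peek(self) -> tuple[str, str]:
        return self.tokens[self.pos]

    def advance(self) -> tuple[str, str]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> Node:
        node = self.parse_or()
        kind, value = self.peek()
        if kind != "END":
            raise ExpressionError(f"unexpected token {value!r}")
        return node

    def parse_or(self) -> Node:
        node = self.parse_and()
        while self.peek()[0] == "OR":
            self.advance()
            node = Or(node, self.parse_and())
        return node

    def parse_and(self) -> Node:
        node = self.parse_not()
        while self.peek()[0] == "AND":
            self.advance()
            node = And(node, self.parse_not())
        return node

    def parse_not(self) -> Node:
        if self.peek()[0] == "NOT":
            self.advance()
            return Not(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> Node:
        kind, value = self.advance()
        if kind == "VAR":
            return Var(value)
        if kind == "CONST":
            return Const(int(value))
        if kind == "(":
            node = self.parse_or()
            if self.advance()[0] != ")":
                raise ExpressionError("missing closing parenthesis")
            return node
        raise ExpressionError(f"unexpected token {value!r}" if value else "unexpected end of expression")


def parse_expression(text: str) -> Node:
    """Parse an expression string into an AST."""
    if not text.strip():
        raise ExpressionError("empty expression")
    return _Parser(text).parse()


def truth_table(expr: Node, parents: list[str]) -> list[int]:
    """Tabulate ``expr`` over all assignments of ``parents``.

    Entry ``i`` is the value when parent ``j`` carries bit ``(i >> j) & 1``.
    """
    table = []
    for index in range(1 << len(parents)):
        assignment = {name: (index >> j) & 1 for j, name in enumerate(parents)}
        table.append(expr.evaluate(assignment))
    return table
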