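"""Boolean expression language for update functions.

Expressions range over network variables, the constants ``true``/``false``
(also ``1``/``0``), the connectives ``!``, ``&``, ``|``, ``^``, ``=>``,
``<=>`` and applications of *uninterpreted functions* (parameters), written
``Name(arg, ...)``.  Identifiers match ``[A-Za-z_][A-Za-z0-9_]*``.

Binding strength, strongest first: ``!``, ``&``, ``|``, ``^``, ``=>``,
``<=>``.  All binary connectives associate to the right, so ``A | B | C``
parses as ``A | (B | C)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping


class ExprError(ValueError):
    """Syntax or resolution error; carries 1-based line/column."""

    def __init__(self, message: str, line: int = 1, column: int = 1):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


class Expr:
    """Base class of expression AST nodes (immutable)."""

    __slots__ = ()


@dataclass(frozen=True)
class Const(Expr):
    value: bool


@dataclass(frozen=True)
class Var(Expr):
    name: str


@dataclass(frozen=True)
class Not(Expr):
    operand: Expr


@dataclass(frozen=True)
class BinOp(Expr):
    op: str  # "and" | "or" | "xor" | "imp" | "iff"
    left: Expr
    right: Expr


@dataclass(frozen=True)
class App(Expr):
    """Application of an uninterpreted function (parameter) to arguments."""

    param: str
    args: tuple[Expr, ...]


def variables_of(e: Expr) -> frozenset[str]:
    """All variable names referenced anywhere in the expression."""
    out: set[str] = set()
    stack = [e]
    while stack:
        node = stack.pop()
        if isinstance(node, Var):
            out.add(node.name)
        elif isinstance(node, Not):
            stack.append(node.operand)
        elif isinstance(node, BinOp):
            stack.append(node.left)
            stack.append(node.right)
        elif isinstance(node, App):
            stack.extend(node.args)
    return frozenset(out)


def parameters_of(e: Expr) -> dict[str, int]:
    """Mapping parameter-name -> arity for every application in the expression.

    Raises :class:`ExprError` if the same name is applied with two arities.
    """
    out: dict[str, int] = {}
    stack = [e]
    while stack:
        node = stack.pop()
        if isinstance(node, Not):
            stack.append(node.operand)
        elif isinstance(node, BinOp):
            stack.append(node.left)
            stack.append(node.right)
        elif isinstance(node, App):
            if node.param in out and out[node.param] != len(node.args):
                raise ExprError(
                    f"parameter {node.param!r} used with inconsistent arities "
                    f"{out[node.param]} and {len(node.args)}"
                )
            out[node.param] = len(node.args)
            stack.extend(node.args)
    return out


_TOKEN_RE = re.compile(
    r"\s+|(?P<id>[A-Za-z_][A-Za-z0-9_]*)|(?P<op><=>|=>|[!&|^(),])|(?P<num>[01])"
)


@dataclass(frozen=True)
class _Token:
    kind: str  # "id" | "op" | "num" | "eof"
    text: str
    line: int
    column: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    line, line_start = 1, 0
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            raise ExprError(
                f"unexpected character {text[pos]!r}", line, pos - line_start + 1
            )
        col = pos - line_start + 1
        if m.lastgroup is not None:
            tokens.append(_Token(m.lastgroup, m.group(), line, col))
        else:
            nl = text.count("\n", pos, m.end())
            if nl:
                line += nl
                line_start = text.rfind("\n", pos, m.end()) + 1
        pos = m.end()
    tokens.append(_Token("eof", "", line, len(text) - line_start + 1))
    return tokens


# binary levels from weakest to strongest binding
_LEVELS = (("<=>", "iff"), ("=>", "imp"), ("^", "xor"), ("|", "or"), ("&", "and"))


class _Parser:
    def __init__(
        self,
        tokens: list[_Token],
        variables: frozenset[str] | None,
        parameters: Mapping[str, int] | None,
        implicit: dict[str, int] | None,
    ):
        self.tokens = tokens
        self.pos = 0
        self.variables = variables
        self.parameters = parameters
        self.implicit = implicit

    def peek(self) -> _Token:
        return self.tokens[self.pos]

    def take(self) -> _Token:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, text: str) -> _Token:
        tok = self.peek()
        if tok.text != text:
            raise ExprError(f"expected {text!r}, found {tok.text or 'end of input'!r}", tok.line, tok.column)
        return self.take()

    def parse(self) -> Expr:
        e = self.binary(0)
        tok = self.peek()
        if tok.kind != "eof":
            raise ExprError(f"unexpected trailing input {tok.text!r}", tok.line, tok.column)
        return e

    def binary(self, level: int) -> Expr:
        if level == len(_LEVELS):
            return self.unary()
        symbol, name = _LEVELS[level]
        left = self.binary(level + 1)
        if self.peek().text == symbol:
            self.take()
            right = self.binary(level)  # right-associative
            return BinOp(name, left, right)
        return left

    def unary(self) -> Expr:
        tok = self.peek()
        if tok.text == "!":
            self.take()
            return Not(self.unary())
        return self.atom()

    def atom(self) -> Expr:
        tok = self.take()
        if tok.text == "(":
            e = self.binary(0)
            self.expect(")")
            return e
        if tok.kind == "num":
            return Const(tok.text == "1")
        if tok.kind == "id":
            if tok.text == "true":
                return Const(True)
            if tok.text == "false":
                return Const(False)
            if self.peek().text == "(":
                return self.application(tok)
            if self.variables is not None and tok.text not in self.variables:
                raise ExprError(f"unknown variable {tok.text!r}", tok.line, tok.column)
            return Var(tok.text)
        raise ExprError(
            f"expected an expression, found {tok.text or 'end of input'!r}",
            tok.line,
            tok.column,
        )

    def application(self, name: _Token) -> Expr:
        self.expect("(")
        args: list[Expr] = []
        if self.peek().text != ")":
            args.append(self.binary(0))
            while self.peek().text == ",":
                self.take()
                args.append(self.binary(0))
        self.expect(")")
        arity = len(args)
        if self.parameters is not None:
            declared = self.parameters.get(name.text)
            if declared is None and self.implicit is None:
                raise ExprError(f"unknown parameter {name.text!r}", name.line, name.column)
            if declared is None and self.implicit is not None:
                declared = self.implicit.setdefault(name.text, arity)
            if declared != arity:
                raise ExprError(
                    f"parameter {name.text!r} declared with arity {declared}, applied to {arity} argument(s)",
                    name.line,
                    name.column,
                )
        elif self.implicit is not None:
            declared = self.implicit.setdefault(name.text, arity)
            if declared != arity:
                raise ExprError(
                    f"parameter {name.text!r} used with inconsistent arities {declared} and {arity}",
                    name.line,
                    name.column,
                )
        return App(name.text, tuple(args))


def parse_expression(
    text: str,
    variables: frozenset[str] | set[str] | None = None,
    parameters: Mapping[str, int] | None = None,
    implicit_parameters: dict[str, int] | None = None,
) -> Expr:
    """Parse an expression, resolving identifiers against declarations.

    ``variables``/``parameters`` of ``None`` disable the respective check.
    When ``implicit_parameters`` is given, applications of undeclared names
    register a new parameter there (with arity consistency enforced), which
    is how the native file format declares parameters on first use.
    """
    if not text.strip():
        raise ExprError("empty expression")
    vars_frozen = frozenset(variables) if variables is not None else None
    parser = _Parser(_tokenize(text), vars_frozen, parameters, implicit_parameters)
    return parser.parse()


_PRINT_LEVEL = {"iff": 0, "imp": 1, "xor": 2, "or": 3, "and": 4}
_PRINT_SYMBOL = {"iff": "<=>", "imp": "=>", "xor": "^", "or": "|", "and": "&"}


def to_text(e: Expr) -> str:
    """Render an expression in the concrete syntax accepted by the parser."""

    def go(node: Expr, level: int) -> str:
        if isinstance(node, Const):
            return "true" if node.value else "false"
        if isinstance(node, Var):
            return node.name
        if isinstance(node, Not):
            return "!" + go(node.operand, 5)
        if isinstance(node, App):
            return f"{node.param}({', '.join(go(a, 0) for a in node.args)})"
        if isinstance(node, BinOp):
            mine = _PRINT_LEVEL[node.op]
            text = (
                f"{go(node.left, mine + 1)} {_PRINT_SYMBOL[node.op]} {go(node.right, mine)}"
            )
            return f"({text})" if mine < level else text
        raise TypeError(f"not an expression node: {node!r}")

    return go(e, 0)
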