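"""Boolean rule expressions and the ``targets, factors`` rule-file dialect.

A rule is a small abstract syntax tree over node identifiers with the
operators NOT (``!``), AND (``&``), OR (``|``), parentheses and the
constants ``0``/``1``.  Precedence is NOT > AND > OR.  The same tree is
evaluated three ways: as a Boolean function (attractor analysis), as a
truth table over its free identifiers (robustness perturbations), and as
a fuzzy-logic input function on [0,1]^n (continuous conversion, with
NOT -> 1-x, AND -> min, OR -> max).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence


class RuleSyntaxError(ValueError):
    """Raised on malformed rule text; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# --- AST -------------------------------------------------------------------


class Expr:
    __slots__ = ()

    def variables(self) -> tuple[str, ...]:
        """Free identifiers in first-appearance order."""
        seen: dict[str, None] = {}
        stack = [self]
        order: list[str] = []

        def walk(e: Expr) -> None:
            if isinstance(e, Var):
                if e.name not in seen:
                    seen[e.name] = None
                    order.append(e.name)
            elif isinstance(e, Not):
                walk(e.arg)
            elif isinstance(e, (And, Or)):
                walk(e.left)
                walk(e.right)

        del stack
        walk(self)
        return tuple(order)

    def evaluate(self, env: Mapping[str, int]) -> int:
        raise NotImplementedError

    def fuzzy(self, env: Mapping[str, float]) -> float:
        """Fuzzy-logic value; coincides with evaluate() on {0,1} inputs."""
        raise NotImplementedError

    def unparse(self) -> str:
        return _unparse(self, 0)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.unparse()!r})"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Expr) and _key(self) == _key(other)

    def __hash__(self) -> int:
        return hash(_key(self))


@dataclass(frozen=True, eq=False)
class Var(Expr):
    name: str

    def evaluate(self, env):
        return int(env[self.name])

    def fuzzy(self, env):
        return float(env[self.name])


@dataclass(frozen=True, eq=False)
class Const(Expr):
    value: int

    def evaluate(self, env):
        return self.value

    def fuzzy(self, env):
        return float(self.value)


@dataclass(frozen=True, eq=False)
class Not(Expr):
    arg: Expr

    def evaluate(self, env):
        return 1 - self.arg.evaluate(env)

    def fuzzy(self, env):
        return 1.0 - self.arg.fuzzy(env)


@dataclass(frozen=True, eq=False)
class And(Expr):
    left: Expr
    right: Expr

    def evaluate(self, env):
        return self.left.evaluate(env) & self.right.evaluate(env)

    def fuzzy(self, env):
        return min(self.left.fuzzy(env), self.right.fuzzy(env))


@dataclass(frozen=True, eq=False)
class Or(Expr):
    left: Expr
    right: Expr

    def evaluate(self, env):
        return self.left.evaluate(env) | self.right.evaluate(env)

    def fuzzy(self, env):
        return max(self.left.fuzzy(env), self.right.fuzzy(env))


def _key(e: Expr):
    if isinstance(e, Var):
        return ("v", e.name)
    if isinstance(e, Const):
        return ("c", e.value)
    if isinstance(e, Not):
        return ("!", _key(e.arg))
    if isinstance(e, And):
        return ("&", _key(e.left), _key(e.right))
    if isinstance(e, Or):
        return ("|", _key(e.left), _key(e.right))
    raise TypeError(e)


# precedence levels: Or=1, And=2, Not=3, atoms=4
def _unparse(e: Expr, parent_prec: int) -> str:
    if isinstance(e, Var):
        return e.name
    if isinstance(e, Const):
        return str(e.value)
    if isinstance(e, Not):
        s = "!" + _unparse(e.arg, 3)
        prec = 3
    elif isinstance(e, And):
        s = f"{_unparse(e.left, 2)} & {_unparse(e.right, 2)}"
        prec = 2
    elif isinstance(e, Or):
        s = f"{_unparse(e.left, 1)} | {_unparse(e.right, 1)}"
        prec = 1
    else:  # pragma: no cover
        raise TypeError(e)
    return f"({s})" if prec < parent_prec else s


# --- parser ----------------------------------------------------------------

_TOKEN = re.compile(r"\s*(?:(?P<id>[A-Za-z_][A-Za-z0-9_./-]*)|(?P<op>[!&|()01]))")


def _tokenize(text: str, line: int | None) -> Iterator[tuple[str, str]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise RuleSyntaxError(
                    f"unexpected character {text[pos:].strip()[0]!r}", line
                )
            return
        if m.group("id"):
            yield ("id", m.group("id"))
        else:
            yield ("op", m.group("op"))
        pos = m.end()


class _Parser:
    def __init__(self, text: str, line: int | None = None):
        self.tokens = list(_tokenize(text, line))
        self.i = 0
        self.line = line

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise RuleSyntaxError("unexpected end of expression", self.line)
        self.i += 1
        return tok

    def parse(self) -> Expr:
        e = self.parse_or()
        if self.peek() is not None:
            raise RuleSyntaxError(
                f"trailing input near {self.peek()[1]!r}", self.line
            )
        return e

    def parse_or(self) -> Expr:
        e = self.parse_and()
        while self.peek() == ("op", "|"):
            self.next()
            e = Or(e, self.parse_and())
        return e

    def parse_and(self) -> Expr:
        e = self.parse_not()
        while self.peek() == ("op", "&"):
            self.next()
            e = And(e, self.parse_not())
        return e

    def parse_not(self) -> Expr:
        if self.peek() == ("op", "!"):
            self.next()
            return Not(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> Expr:
        kind, val = self.next()
        if kind == "id":
            return Var(val)
        if val == "0":
            return Const(0)
        if val == "1":
            return Const(1)
        if val == "(":
            e = self.parse_or()
            if self.next() != ("op", ")"):
                raise RuleSyntaxError("expected ')'", self.line)
            return e
        raise RuleSyntaxError(f"unexpected token {val!r}", self.line)


def parse_expression(text: str, line: int | None = None) -> Expr:
    """Parse a single rule expression."""
    return _Parser(text, line).parse()


def truth_table(expr: Expr, inputs: Sequence[str]) -> list[int]:
    """Output column over all assignments to ``inputs``.

    Entry ``k`` is the value when input ``i`` takes bit ``i`` of ``k``
    (input 0 is the least significant bit).
    """
    out = []
    for k in range(1 << len(inputs)):
        env = {name: (k >> i) & 1 for i, name in enumerate(inputs)}
        out.append(expr.evaluate(env))
    return out
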