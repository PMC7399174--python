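"""Boolean expression trees for logical rules.

Expressions are built from variables, constants and the connectives
AND (``&``), OR (``|``) and NOT (``!``).  Square brackets are accepted as
grouping symbols interchangeably with parentheses, matching the notation
commonly used for hand-written rule edits (e.g. ``[(mTORC2_c | ILK) & PIP3]
& !PPP1CA``).

A variable evaluates to True when the referenced node's level is >= 1,
which is the threshold semantics used throughout the package for
multi-valued nodes appearing in Boolean contexts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping


class ExprError(ValueError):
    """Raised for malformed expression strings."""


class Expr:
    """Base class for Boolean expression nodes."""

    def evaluate(self, active: Callable[[str], bool]) -> bool:
        raise NotImplementedError

    def variables(self) -> frozenset[str]:
        raise NotImplementedError

    def substitute(self, mapping: Mapping[str, "Expr"]) -> "Expr":
        raise NotImplementedError

    def polarities(self) -> dict[str, set[int]]:
        """Map each variable to the sign(s) of its occurrences.

        +1 for occurrences under an even number of negations, -1 for odd.
        A variable appearing both ways maps to {+1, -1} (dual regulation).
        """
        out: dict[str, set[int]] = {}
        self._collect_polarity(+1, out)
        return out

    def _collect_polarity(self, sign: int, out: dict[str, set[int]]) -> None:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self})"


@dataclass(frozen=True)
class Var(Expr):
    name: str

    def evaluate(self, active):
        return bool(active(self.name))

    def variables(self):
        return frozenset((self.name,))

    def substitute(self, mapping):
        return mapping.get(self.name, self)

    def _collect_polarity(self, sign, out):
        out.setdefault(self.name, set()).add(sign)

    def __str__(self):
        return self.name


@dataclass(frozen=True)
class Const(Expr):
    value: bool

    def evaluate(self, active):
        return self.value

    def variables(self):
        return frozenset()

    def substitute(self, mapping):
        return self

    def _collect_polarity(self, sign, out):
        pass

    def __str__(self):
        return "1" if self.value else "0"


TRUE = Const(True)
FALSE = Const(False)


@dataclass(frozen=True)
class Not(Expr):
    child: Expr

    def evaluate(self, active):
        return not self.child.evaluate(active)

    def variables(self):
        return self.child.variables()

    def substitute(self, mapping):
        return negate(self.child.substitute(mapping))

    def _collect_polarity(self, sign, out):
        self.child._collect_polarity(-sign, out)

    def __str__(self):
        if isinstance(self.child, (Var, Const, Not)):
            return f"!{self.child}"
        return f"!({self.child})"


@dataclass(frozen=True)
class And(Expr):
    children: tuple[Expr, ...]

    def evaluate(self, active):
        return all(c.evaluate(active) for c in self.children)

    def variables(self):
        return frozenset().union(*(c.variables() for c in self.children))

    def substitute(self, mapping):
        return conj([c.substitute(mapping) for c in self.children])

    def _collect_polarity(self, sign, out):
        for c in self.children:
            c._collect_polarity(sign, out)

    def __str__(self):
        parts = []
        for c in self.children:
            if isinstance(c, Or):
                parts.append(f"({c})")
            else:
                parts.append(str(c))
        return " & ".join(parts)


@dataclass(frozen=True)
class Or(Expr):
    children: tuple[Expr, ...]

    def evaluate(self, active):
        return any(c.evaluate(active) for c in self.children)

    def variables(self):
        return frozenset().union(*(c.variables() for c in self.children))

    def substitute(self, mapping):
        return disj([c.substitute(mapping) for c in self.children])

    def _collect_polarity(self, sign, out):
        for c in self.children:
            c._collect_polarity(sign, out)

    def __str__(self):
        return " | ".join(str(c) for c in self.children)


def negate(e: Expr) -> Expr:
    if isinstance(e, Const):
        return Const(not e.value)
    if isinstance(e, Not):
        return e.child
    return Not(e)


def conj(parts: Iterable[Expr]) -> Expr:
    """AND with constant folding and flattening."""
    flat: list[Expr] = []
    for p in parts:
        if isinstance(p, Const):
            if not p.value:
                return FALSE
            continue
        if isinstance(p, And):
            flat.extend(p.children)
        else:
            flat.append(p)
    if not flat:
        return TRUE
    if len(flat) == 1:
        return flat[0]
    return And(tuple(flat))


def disj(parts: Iterable[Expr]) -> Expr:
    """OR with constant folding and flattening."""
    flat: list[Expr] = []
    for p in parts:
        if isinstance(p, Const):
            if p.value:
                return TRUE
            continue
        if isinstance(p, Or):
            flat.extend(p.children)
        else:
            flat.append(p)
    if not flat:
        return FALSE
    if len(flat) == 1:
        return flat[0]
    return Or(tuple(flat))


_TOKEN = re.compile(r"\s*(?:(?P<name>[A-Za-z_][\w.\-]*)|(?P<num>[01])|(?P<op>[&|!()\[\]]))")


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ExprError(f"unexpected character {text[pos]!r} at position {pos}")
        tokens.append(m.group().strip())
        pos = m.end()
    return tokens


def parse_expr(text: str) -> Expr:
    """Parse a rule expression over ``& | ! ( ) [ ]`` with `!` binding tightest."""
    tokens = _tokenize(text)
    if not tokens:
        raise ExprError("empty expression")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> Expr:
        parts = [parse_and()]
        while peek() == "|":
            take()
            parts.append(parse_and())
        return disj(parts)

    def parse_and() -> Expr:
        parts = [parse_atom()]
        while peek() == "&":
            take()
            parts.append(parse_atom())
        return conj(parts)

    def parse_atom() -> Expr:
        tok = peek()
        if tok is None:
            raise ExprError("unexpected end of expression")
        if tok == "!":
            take()
            return negate(parse_atom())
        if tok in "([":
            closer = ")" if tok == "(" else "]"
            take()
            inner = parse_or()
            if peek() != closer:
                raise ExprError(f"expected {closer!r}")
            take()
            return inner
        if tok in ("0", "1"):
            take()
            return Const(tok == "1")
        if tok in ")]&|":
            raise ExprError(f"unexpected token {tok!r}")
        take()
        return Var(tok)

    result = parse_or()
    if pos != len(tokens):
        raise ExprError(f"trailing tokens starting at {tokens[pos]!r}")
    return result
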