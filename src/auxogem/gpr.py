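"""Gene-protein-reaction (GPR) boolean rules.

A GPR is a boolean expression over gene identifiers: ``or`` joins
isoenzymes (any one suffices), ``and`` joins complex subunits (all are
required).  A reaction carries flux after a set of gene deletions iff its
GPR still evaluates true with the deleted genes set to false.  The empty
expression means the reaction is not gene-controlled and is always active.

Expressions are immutable n-ary trees.  The parser accepts the infix
grammar used by SBML-fbc renderings: case-insensitive ``and``/``or``
keywords, parentheses, and bare gene identifiers; ``and`` binds tighter
than ``or``.  Rendered strings always parenthesize nested sub-expressions,
so ``parse(render(e)) == e`` (n-ary nodes absorb associativity).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "GprExpr",
    "GprEmpty",
    "GprGene",
    "GprAnd",
    "GprOr",
    "GprParseError",
    "EMPTY_GPR",
    "parse_gpr",
    "render_gpr",
    "eval_gpr",
    "gpr_genes",
]


class GprExpr:
    """Base class for GPR expression nodes."""

    __slots__ = ()

    def __str__(self) -> str:
        return render_gpr(self)


@dataclass(frozen=True, slots=True)
class GprEmpty(GprExpr):
    """The distinguished empty rule: reaction not under gene control."""


@dataclass(frozen=True, slots=True)
class GprGene(GprExpr):
    gene: str


@dataclass(frozen=True, slots=True)
class GprAnd(GprExpr):
    args: tuple[GprExpr, ...]


@dataclass(frozen=True, slots=True)
class GprOr(GprExpr):
    args: tuple[GprExpr, ...]


EMPTY_GPR = GprEmpty()


class GprParseError(ValueError):
    """Raised for malformed GPR text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(text)]


class _Parser:
    """Recursive-descent parser: expr := term ('or' term)*;
    term := atom ('and' atom)*; atom := '(' expr ')' | gene."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> tuple[str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise GprParseError("unexpected end of expression", len(self.text))
        self.pos += 1
        return tok

    def parse(self) -> GprExpr:
        expr = self.expr()
        tok = self.peek()
        if tok is not None:
            raise GprParseError(f"unexpected token {tok[0]!r}", tok[1])
        return expr

    def expr(self) -> GprExpr:
        parts = [self.term()]
        while (tok := self.peek()) is not None and tok[0].lower() == "or":
            self.next()
            parts.append(self.term())
        return parts[0] if len(parts) == 1 else GprOr(tuple(_flatten(parts, GprOr)))

    def term(self) -> GprExpr:
        parts = [self.atom()]
        while (tok := self.peek()) is not None and tok[0].lower() == "and":
            self.next()
            parts.append(self.atom())
        return parts[0] if len(parts) == 1 else GprAnd(tuple(_flatten(parts, GprAnd)))

    def atom(self) -> GprExpr:
        tok, at = self.next()
        if tok == "(":
            inner = self.expr()
            closing = self.peek()
            if closing is None or closing[0] != ")":
                raise GprParseError("unbalanced parenthesis", at)
            self.next()
            return inner
        if tok == ")":
            raise GprParseError("unmatched closing parenthesis", at)
        if tok.lower() in ("and", "or"):
            raise GprParseError(f"dangling operator {tok!r}", at)
        return GprGene(tok)


def _flatten(parts: list[GprExpr], node_type: type) -> Iterator[GprExpr]:
    # absorb same-type children so associativity cannot distinguish trees
    for p in parts:
        if isinstance(p, node_type):
            yield from p.args
        else:
            yield p


def parse_gpr(text: str) -> GprExpr:
    """Parse a GPR rule string into an expression tree.

    Empty or whitespace-only text yields the empty expression.
    Raises :class:`GprParseError` on malformed input.
    """
    if not text or not text.strip():
        return EMPTY_GPR
    return _Parser(text).parse()


def render_gpr(expr: GprExpr) -> str:
    """Render an expression as an unambiguous rule string.

    Composite sub-expressions are always parenthesized, e.g.
    ``(YGL125W and YPL023C) or YGL125W``.
    """
    if isinstance(expr, GprEmpty):
        return ""
    if isinstance(expr, GprGene):
        return expr.gene
    if isinstance(expr, GprAnd):
        return " and ".join(_render_child(a) for a in expr.args)
    if isinstance(expr, GprOr):
        return " or ".join(_render_child(a) for a in expr.args)
    raise TypeError(f"not a GPR expression: {expr!r}")


def _render_child(expr: GprExpr) -> str:
    if isinstance(expr, (GprAnd, GprOr)):
        return f"({render_gpr(expr)})"
    return render_gpr(expr)


def eval_gpr(expr: GprExpr, deleted: frozenset[str] | set[str]) -> bool:
    """Evaluate a rule under a gene deletion.

    Deleted genes are false, all others true; the empty expression is
    true (a reaction without gene control survives any knockout).
    """
    if isinstance(expr, GprEmpty):
        return True
    if isinstance(expr, GprGene):
        return expr.gene not in deleted
    if isinstance(expr, GprAnd):
        return all(eval_gpr(a, deleted) for a in expr.args)
    if isinstance(expr, GprOr):
        return any(eval_gpr(a, deleted) for a in expr.args)
    raise TypeError(f"not a GPR expression: {expr!r}")


def gpr_genes(expr: GprExpr) -> frozenset[str]:
    """All gene identifiers appearing in the expression."""
    if isinstance(expr, GprEmpty):
        return frozenset()
    if isinstance(expr, GprGene):
        return frozenset((expr.gene,))
    if isinstance(expr, (GprAnd, GprOr)):
        return frozenset(itertools.chain.from_iterable(gpr_genes(a) for a in expr.args))
    raise TypeError(f"not a GPR expression: {expr!r}")
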