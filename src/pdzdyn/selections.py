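"""Minimal atom-selection grammar.

Supports the handful of predicates the analyses need::

    resid 320              residue number
    resid 266-277          inclusive residue-number range
    resname SEP            3-letter residue name
    name CA                atom name
    chain A                chain identifier
    not <expr>, ( <expr> ) boolean combinators with AND binding
    <expr> and <expr>      tighter than OR
    <expr> or <expr>

Resolution against a :class:`~pdzdyn.trajectory.Topology` is a pure
function returning a sorted, deduplicated atom-index array; an empty
result is valid (e.g. a residue number that does not exist).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Topology

__all__ = ["AtomSelection", "SelectionError", "resolve_selection"]


class SelectionError(ValueError):
    """Selection string does not parse or uses an unknown keyword."""


_KEYWORDS = {"resid", "resname", "name", "chain"}


def _tokenize(expression: str) -> list[str]:
    out, cur = [], ""
    for ch in expression:
        if ch in "()":
            if cur:
                out.append(cur)
                cur = ""
            out.append(ch)
        elif ch.isspace():
            if cur:
                out.append(cur)
                cur = ""
        else:
            cur += ch
    if cur:
        out.append(cur)
    return out


class _Parser:
    def __init__(self, expression: str):
        self.expression = expression
        self.tokens = _tokenize(expression)
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def advance(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError(f"unexpected end of selection {self.expression!r}")
        self.pos += 1
        return tok

    def fail(self, msg: str):
        raise SelectionError(f"{msg} at token {self.pos} in {self.expression!r}")

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            self.fail(f"trailing token {self.peek()!r}")
        return node

    def expr(self):
        node = self.term()
        while self.peek() == "or":
            self.advance()
            node = ("or", node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek() == "and":
            self.advance()
            node = ("and", node, self.factor())
        return node

    def factor(self):
        tok = self.peek()
        if tok == "(":
            self.advance()
            node = self.expr()
            if self.advance() != ")":
                self.fail("expected closing parenthesis")
            return node
        if tok == "not":
            self.advance()
            return ("not", self.factor())
        return self.primary()

    def primary(self):
        kw = self.advance()
        if kw not in _KEYWORDS:
            self.fail(f"unknown keyword {kw!r}")
        value = self.advance()
        if kw == "resid":
            try:
                if "-" in value[1:]:
                    lo, hi = value.rsplit("-", 1)
                    return ("resid", int(lo), int(hi))
                return ("resid", int(value), int(value))
            except ValueError:
                self.fail(f"bad residue id or range {value!r}")
        return (kw, value)


@dataclass(frozen=True)
class AtomSelection:
    """A parsed selection expression; hashable and reusable across topologies."""

    expression: str

    def __post_init__(self):
        object.__setattr__(self, "_ast", _Parser(self.expression).parse())

    def resolve(self, top: Topology) -> np.ndarray:
        mask = _eval(self._ast, top)
        return np.flatnonzero(mask)

    def __str__(self) -> str:
        return self.expression


def _eval(node, top: Topology) -> np.ndarray:
    op = node[0]
    if op == "or":
        return _eval(node[1], top) | _eval(node[2], top)
    if op == "and":
        return _eval(node[1], top) & _eval(node[2], top)
    if op == "not":
        return ~_eval(node[1], top)
    if op == "resid":
        return (top.residue_numbers >= node[1]) & (top.residue_numbers <= node[2])
    if op == "resname":
        return top.residue_names == node[1]
    if op == "name":
        return top.atom_names == node[1]
    if op == "chain":
        return top.chain_ids == node[1]
    raise AssertionError(f"unreachable node {node!r}")


def resolve_selection(sel: AtomSelection | str, top: Topology) -> np.ndarray:
    """Resolve a selection (or raw expression) to sorted atom indices."""
    if isinstance(sel, str):
        sel = AtomSelection(sel)
    return sel.resolve(top)
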