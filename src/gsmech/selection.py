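"""A minimal atom-selection grammar.

The grammar is intentionally small and owned by this package::

    expr     := or_expr
    or_expr  := and_expr ( "or" and_expr )*
    and_expr := unary ( "and" unary )*
    unary    := "not" unary | "(" expr ")" | term
    term     := "resid"   (N | N-M)+
              | "resname" NAME+
              | "name"    NAME+
              | "chain"   NAME+
              | "element" NAME+
              | "water" | "all" | "none"

Selections resolve to a deterministic, duplicate-free, topology-ordered
index list. An unknown residue name yields an empty selection plus a
warning; a malformed expression raises :class:`SelectionSyntaxError` with
the offending position.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np

from .topology import Topology

_KEYWORDS = {"resid", "resname", "name", "chain", "element",
             "water", "all", "none", "and", "or", "not", "(", ")"}


class SelectionSyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at token position {position})")
        self.position = position


@dataclass(frozen=True)
class Selection:
    """A parsed-on-demand selection expression."""

    expression: str

    def resolve(self, topology: Topology) -> np.ndarray:
        return select(topology, self.expression)


def _tokenize(expression: str) -> list[str]:
    out = []
    for raw in re.findall(r"\(|\)|[^\s()]+", expression):
        out.append(raw)
    return out


class _Parser:
    def __init__(self, tokens: list[str], topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.topo = topology

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def advance(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression", self.pos)
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise SelectionSyntaxError(f"unexpected token {self.peek()!r}", self.pos)
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.advance()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() == "and":
            self.advance()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.advance()
            return ~self.unary()
        if tok == "(":
            self.advance()
            mask = self.or_expr()
            if self.peek() != ")":
                raise SelectionSyntaxError("expected ')'", self.pos)
            self.advance()
            return mask
        return self.term()

    def _values(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            vals.append(self.advance())
        if not vals:
            raise SelectionSyntaxError("keyword requires at least one value", self.pos)
        return vals

    def term(self) -> np.ndarray:
        tok = self.advance()
        topo = self.topo
        n = topo.n_atoms
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "none":
            return np.zeros(n, dtype=bool)
        if tok == "water":
            return topo.is_water()
        if tok == "resid":
            mask = np.zeros(n, dtype=bool)
            for val in self._values():
                m = re.fullmatch(r"(-?\d+)-(-?\d+)", val)
                if m:
                    lo, hi = int(m.group(1)), int(m.group(2))
                    mask |= (topo.res_ids >= lo) & (topo.res_ids <= hi)
                elif re.fullmatch(r"-?\d+", val):
                    mask |= topo.res_ids == int(val)
                else:
                    raise SelectionSyntaxError(
                        f"bad residue id/range {val!r}", self.pos - 1)
            return mask
        if tok == "resname":
            vals = [v.upper() for v in self._values()]
            known = set(np.char.upper(topo.res_names))
            unknown = [v for v in vals if v not in known]
            if unknown:
                warnings.warn(f"unknown residue name(s) {unknown}; empty match")
            return np.isin(np.char.upper(topo.res_names), vals)
        if tok == "name":
            vals = [v.upper() for v in self._values()]
            return np.isin(np.char.upper(topo.atom_names), vals)
        if tok == "chain":
            return np.isin(topo.chain_ids, self._values())
        if tok == "element":
            vals = [v.capitalize() for v in self._values()]
            return np.isin(topo.elements, vals)
        raise SelectionSyntaxError(f"unknown keyword {tok!r}", self.pos - 1)


def select_mask(topology: Topology, expression: str) -> np.ndarray:
    """Boolean atom mask for a selection expression."""
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionSyntaxError("empty selection expression", 0)
    return _Parser(tokens, topology).parse()


def select(topology: Topology, expression: str) -> np.ndarray:
    """Topology-ordered, duplicate-free atom indices matching ``expression``."""
    return np.flatnonzero(select_mask(topology, expression))
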