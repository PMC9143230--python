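"""Atom-selection mini-language.

Grammar (lowest to highest precedence)::

    expr    := term ("or" term)*
    term    := factor ("and" factor)*
    factor  := "not" factor | "(" expr ")" | primary
    primary := "name" GLOB | "molname" GLOB | "molid" RANGES

GLOB is a shell-style pattern (``O*``, ``HW?``); RANGES is a comma list of
molecule ids or inclusive id ranges (``1-5,8``), 0-based as everywhere in
the library.  Resolution is deterministic: the resolved ids are returned
sorted ascending.
"""

from __future__ import annotations

import fnmatch
import re
from dataclasses import dataclass

import numpy as np

from .core import Topology


class SelectionError(ValueError):
    """Syntax or resolution error; carries the offending position."""


@dataclass(frozen=True)
class AtomSelection:
    """A resolved selection: the source expression plus sorted atom ids."""

    expression: str
    atom_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.atom_ids)

    @property
    def empty(self) -> bool:
        return len(self.atom_ids) == 0


_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")

_KEYWORDS = {"and", "or", "not", "name", "molname", "molid", "(", ")"}


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN.match(expression, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser producing boolean atom masks directly."""

    def __init__(self, tokens: list[tuple[str, int]], topology: Topology, expression: str):
        self.tokens = tokens
        self.i = 0
        self.top = topology
        self.expr = expression

    def _peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def _next(self) -> tuple[str, int]:
        if self.i >= len(self.tokens):
            raise SelectionError(
                f"unexpected end of selection {self.expr!r} (position {len(self.expr)})"
            )
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def _fail(self, msg: str, pos: int) -> None:
        raise SelectionError(f"{msg} in {self.expr!r} at position {pos}")

    def parse(self) -> np.ndarray:
        mask = self.expr_or()
        if self.i < len(self.tokens):
            tok, pos = self.tokens[self.i]
            self._fail(f"unexpected token {tok!r}", pos)
        return mask

    def expr_or(self) -> np.ndarray:
        mask = self.expr_and()
        while self._peek() == "or":
            self._next()
            mask = mask | self.expr_and()
        return mask

    def expr_and(self) -> np.ndarray:
        mask = self.factor()
        while self._peek() == "and":
            self._next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok, pos = self._next()
        if tok == "not":
            return ~self.factor()
        if tok == "(":
            mask = self.expr_or()
            closing, cpos = self._next()
            if closing != ")":
                self._fail(f"expected ')', got {closing!r}", cpos)
            return mask
        if tok in ("name", "molname"):
            pat, ppos = self._next()
            if pat in _KEYWORDS:
                self._fail(f"{tok} requires a pattern, got keyword {pat!r}", ppos)
            field = self.top.names if tok == "name" else self.top.molecule_names
            return np.array(
                [fnmatch.fnmatchcase(str(v), pat) for v in field], dtype=bool
            )
        if tok == "molid":
            spec, spos = self._next()
            ids = self._parse_ranges(spec, spos)
            return np.isin(self.top.molecule_ids, ids)
        self._fail(f"unexpected token {tok!r}", pos)
        raise AssertionError  # unreachable

    def _parse_ranges(self, spec: str, pos: int) -> np.ndarray:
        out: list[int] = []
        for part in spec.split(","):
            m = re.fullmatch(r"(\d+)(?:-(\d+))?", part)
            if m is None:
                self._fail(f"bad molid range {part!r}", pos)
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            if hi < lo:
                self._fail(f"descending molid range {part!r}", pos)
            out.extend(range(lo, hi + 1))
        return np.array(sorted(set(out)), dtype=np.int64)


def select(topology: Topology, expression: str) -> AtomSelection:
    """Resolve a selection expression against a topology.

    Empty results are allowed (callers that need atoms check
    :attr:`AtomSelection.empty`); syntax errors raise
    :class:`SelectionError` with the offending position.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError(f"empty selection expression {expression!r}")
    mask = _Parser(tokens, topology, expression).parse()
    return AtomSelection(expression=expression, atom_ids=np.nonzero(mask)[0])
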