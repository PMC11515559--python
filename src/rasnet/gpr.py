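"""Gene-protein-reaction (GPR) rules.

A GPR rule is a boolean expression tree linking gene products to the
catalysis of a reaction.  Internal nodes are the operators ``ALL`` (AND
semantics: the genes encode subunits of one enzyme complex) and ``ANY``
(OR semantics: the genes encode isoenzymes); leaves are gene identifiers.
Rules are parsed from the usual textual dialect, e.g. ``"(A and B) or C"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

__all__ = ["GPRRule", "GPRParseError", "parse_gpr"]


class GPRParseError(ValueError):
    """Raised when a GPR expression string cannot be parsed."""


@dataclass(frozen=True)
class GPRRule:
    """Immutable GPR expression tree.

    Exactly one of two shapes: a leaf (``gene`` set, no children) or an
    operator node (``op`` in {"ALL", "ANY"} with >= 2 children).
    """

    op: str | None = None
    gene: str | None = None
    children: tuple["GPRRule", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.op is None:
            if not self.gene:
                raise ValueError("leaf rule requires a non-empty gene id")
            if self.children:
                raise ValueError("leaf rule cannot have children")
        else:
            if self.op not in ("ALL", "ANY"):
                raise ValueError(f"unknown operator {self.op!r}")
            if len(self.children) < 2:
                raise ValueError("operator nodes require at least 2 children")
            if self.gene is not None:
                raise ValueError("operator node cannot carry a gene id")

    # -- constructors -------------------------------------------------

    @classmethod
    def leaf(cls, gene: str) -> "GPRRule":
        return cls(gene=gene)

    @classmethod
    def all_of(cls, *rules: "GPRRule") -> "GPRRule":
        return cls._combine("ALL", rules)

    @classmethod
    def any_of(cls, *rules: "GPRRule") -> "GPRRule":
        return cls._combine("ANY", rules)

    @classmethod
    def _combine(cls, op: str, rules: tuple["GPRRule", ...]) -> "GPRRule":
        # flatten nested same-operator nodes so ANY(ANY(a,b),c) == ANY(a,b,c)
        flat: list[GPRRule] = []
        for r in rules:
            if r.op == op:
                flat.extend(r.children)
            else:
                flat.append(r)
        if len(flat) == 1:
            return flat[0]
        return cls(op=op, children=tuple(flat))

    # -- inspection ---------------------------------------------------

    @property
    def is_leaf(self) -> bool:
        return self.op is None

    @property
    def genes(self) -> frozenset[str]:
        """Set of all gene identifiers appearing in the rule."""
        if self.is_leaf:
            return frozenset([self.gene])  # type: ignore[list-item]
        out: frozenset[str] = frozenset()
        for c in self.children:
            out |= c.genes
        return out

    @property
    def classification(self) -> str:
        """One of ``single``, ``AND``, ``OR``, ``nested``."""
        if self.is_leaf:
            return "single"
        if all(c.is_leaf for c in self.children):
            return "AND" if self.op == "ALL" else "OR"
        return "nested"

    def walk(self) -> Iterator["GPRRule"]:
        yield self
        for c in self.children:
            yield from c.walk()

    # -- serialization ------------------------------------------------

    def to_string(self) -> str:
        """Textual form that :func:`parse_gpr` parses back to an equal tree."""
        if self.is_leaf:
            return self.gene  # type: ignore[return-value]
        if self.op == "ALL":
            parts = [
                f"({c.to_string()})" if c.op == "ANY" else c.to_string()
                for c in self.children
            ]
            return " and ".join(parts)
        parts = [
            f"({c.to_string()})" if c.op == "ALL" else c.to_string()
            for c in self.children
        ]
        return " or ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


def parse_gpr(text: str) -> GPRRule:
    """Parse a boolean GPR string into a :class:`GPRRule`.

    ``and`` binds tighter than ``or`` (case-insensitive keywords);
    parentheses override precedence.  Every other token is a gene id.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GPRParseError(f"empty GPR expression: {text!r}")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPRRule:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            advance()
            terms.append(parse_and())
        return GPRRule.any_of(*terms) if len(terms) > 1 else terms[0]

    def parse_and() -> GPRRule:
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            advance()
            factors.append(parse_atom())
        return GPRRule.all_of(*factors) if len(factors) > 1 else factors[0]

    def parse_atom() -> GPRRule:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of expression: {text!r}")
        if tok == "(":
            advance()
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in {text!r}")
            advance()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r} in {text!r}")
        return GPRRule.leaf(advance())

    rule = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens after position {pos} in {text!r}")
    return rule
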