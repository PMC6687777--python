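"""Gene-protein-reaction (GPR) boolean rules.

A GPR is a monotone boolean formula over gene identifiers in which AND nodes
represent enzyme complexes (every subunit required) and OR nodes represent
isoenzymes (any one gene suffices).  Negation does not occur.  The empty rule
means the reaction is not gene-associated (spontaneous, transport without a
known carrier, exchange or pseudo-reaction) and always evaluates true.

Rules serialize to and from the conventional infix text used by SBML/FBC and
cobrapy, e.g. ``"(A and B) or (C and B)"``, with AND binding tighter than OR.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

__all__ = ["GPRExpression", "GPRParseError", "parse_gpr", "evaluate_gpr", "prune_gpr"]


class GPRParseError(ValueError):
    """Raised for malformed infix GPR text; carries the offending token position."""


# Internal tree representation: a node is either a gene id (str) or a tuple
# (op, children) with op in {"and", "or"} and len(children) >= 2.  Nodes are
# normalized: an "and" node never has an "and" child, likewise for "or".
Node = "str | tuple"


def _flatten(op: str, children) -> "Node":
    flat: list = []
    for child in children:
        if isinstance(child, tuple) and child[0] == op:
            flat.extend(child[1])
        else:
            flat.append(child)
    if len(flat) == 1:
        return flat[0]
    return (op, tuple(flat))


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> Iterator[tuple[str, int]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:  # only trailing whitespace remains
            break
        yield m.group(1), m.start(1)
        pos = m.end()


@dataclass(frozen=True)
class GPRExpression:
    """A parsed GPR rule; ``root is None`` for the empty (no-association) rule."""

    root: "Node | None" = None

    @classmethod
    def from_string(cls, text: str) -> "GPRExpression":
        return parse_gpr(text)

    @classmethod
    def single(cls, gene: str) -> "GPRExpression":
        return cls(gene)

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> frozenset:
        """All gene ids appearing as leaves."""
        out: set = set()

        def walk(node):
            if isinstance(node, str):
                out.add(node)
            elif node is not None:
                for child in node[1]:
                    walk(child)

        walk(self.root)
        return frozenset(out)

    def evaluate(self, present) -> bool:
        return evaluate_gpr(self, present)

    def prune(self, present) -> "GPRExpression":
        return prune_gpr(self, present)

    def substitute(self, mapping: dict) -> "GPRExpression":
        """Rename leaves via ``mapping`` (ids not in the mapping are kept)."""

        def walk(node):
            if isinstance(node, str):
                return mapping.get(node, node)
            return _flatten(node[0], tuple(walk(c) for c in node[1]))

        if self.root is None:
            return self
        return GPRExpression(walk(self.root))

    def to_string(self) -> str:
        def render(node, parent_op=None) -> str:
            if isinstance(node, str):
                return node
            op, children = node
            text = f" {op} ".join(render(c, op) for c in children)
            # Parenthesize an OR group under an AND parent; also parenthesize
            # AND groups under OR for readability (matches the field's style).
            if parent_op is not None and op != parent_op:
                return f"({text})"
            return text

        if self.root is None:
            return ""
        return render(self.root)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def parse_gpr(text: str) -> GPRExpression:
    """Parse infix boolean text over gene ids with ``and``/``or`` keywords.

    AND binds tighter than OR; parentheses override.  The empty string parses
    to the empty expression.  Keywords are case-insensitive.
    """
    tokens = list(_tokenize(text))
    if not tokens:
        return GPRExpression(None)
    idx = 0

    def peek():
        return tokens[idx][0] if idx < len(tokens) else None

    def error(msg: str):
        pos = tokens[idx][1] if idx < len(tokens) else len(text)
        raise GPRParseError(f"{msg} at position {pos} in GPR {text!r}")

    def parse_or():
        nonlocal idx
        parts = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            idx += 1
            parts.append(parse_and())
        return _flatten("or", parts)

    def parse_and():
        nonlocal idx
        parts = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            idx += 1
            parts.append(parse_atom())
        return _flatten("and", parts)

    def parse_atom():
        nonlocal idx
        tok = peek()
        if tok is None:
            error("unexpected end of expression")
        if tok == "(":
            idx += 1
            inner = parse_or()
            if peek() != ")":
                error("expected ')'")
            idx += 1
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            error(f"unexpected token {tok!r}")
        idx += 1
        return tok

    root = parse_or()
    if idx != len(tokens):
        error(f"unexpected token {tokens[idx][0]!r}")
    return GPRExpression(root)


def evaluate_gpr(expr: GPRExpression, present) -> bool:
    """Boolean value of ``expr`` with genes in ``present`` true, others false.

    The empty expression evaluates true (non-gene-associated reactions are
    always retained when carving).
    """
    present = set(present)

    def walk(node) -> bool:
        if isinstance(node, str):
            return node in present
        op, children = node
        if op == "and":
            return all(walk(c) for c in children)
        return any(walk(c) for c in children)

    if expr.root is None:
        return True
    return walk(expr.root)


def prune_gpr(expr: GPRExpression, present) -> GPRExpression:
    """Restrict ``expr`` to the genes in ``present``.

    Absent OR-alternatives (isoenzymes) are dropped; an AND clause (complex)
    with any absent subunit is dropped as a whole.  The result is logically
    equivalent to ``expr`` with absent genes fixed to false.  Requires that
    ``expr`` still evaluates true under ``present``.
    """
    present = set(present)
    if not evaluate_gpr(expr, present):
        raise ValueError(
            "cannot prune a GPR that evaluates false for the given gene set: "
            f"{expr.to_string()!r}"
        )
    if expr.root is None:
        return expr

    def walk(node):
        # Returns a pruned node, or None when the subtree is false.
        if isinstance(node, str):
            return node if node in present else None
        op, children = node
        kept = []
        for child in children:
            sub = walk(child)
            if sub is None:
                if op == "and":
                    return None
            else:
                kept.append(sub)
        if not kept:
            return None
        return _flatten(op, kept)

    return GPRExpression(walk(expr.root))
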