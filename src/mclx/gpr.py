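"""Gene-protein-reaction (GPR) rule parsing and evaluation.

GPR rules are Boolean AND/OR expressions over gene identifiers, e.g.
``(g1 and g2) or g3`` meaning the reaction is catalysed either by the
g1/g2 complex or by the g3 isozyme.  Two evaluations are needed:

* Boolean presence/absence, for knockout simulation;
* a three-valued regulation direction (down < unchanged < up), where AND
  takes the most restrictive branch (a complex is limited by its scarcest
  subunit) and OR the least restrictive one (an isozyme rescues).

Gene tokens may contain dots, dashes and digits, so rules are parsed with a
small recursive-descent parser rather than reusing a Python-expression
parser.  ``and``/``or`` are matched case-insensitively; ``&``/``|`` are
accepted as synonyms.
"""

from __future__ import annotations

import re
from collections.abc import Callable, Mapping

__all__ = ["parse_gpr", "genes_in", "eval_bool", "eval_direction", "GPRSyntaxError"]


class GPRSyntaxError(ValueError):
    pass


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

# AST: ("gene", id) | ("and", [nodes]) | ("or", [nodes])
Node = tuple


def _tokens(rule: str) -> list[str]:
    return _TOKEN_RE.findall(rule)


class _Parser:
    def __init__(self, tokens: list[str], rule: str):
        self.tokens = tokens
        self.pos = 0
        self.rule = rule

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of GPR rule {self.rule!r}")
        self.pos += 1
        return tok

    def parse_or(self) -> Node:
        parts = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() in ("or", "|"):
            self.next()
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else ("or", parts)

    def parse_and(self) -> Node:
        parts = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() in ("and", "&"):
            self.next()
            parts.append(self.parse_atom())
        return parts[0] if len(parts) == 1 else ("and", parts)

    def parse_atom(self) -> Node:
        tok = self.next()
        if tok == "(":
            node = self.parse_or()
            if self.next() != ")":
                raise GPRSyntaxError(f"missing ')' in GPR rule {self.rule!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or", "&", "|"):
            raise GPRSyntaxError(f"unexpected {tok!r} in GPR rule {self.rule!r}")
        return ("gene", tok)


def parse_gpr(rule: str) -> Node | None:
    """Parse a GPR rule into an AST; empty/blank rules parse to ``None``."""
    rule = rule.strip()
    if not rule:
        return None
    parser = _Parser(_tokens(rule), rule)
    node = parser.parse_or()
    if parser.peek() is not None:
        raise GPRSyntaxError(f"trailing tokens in GPR rule {rule!r}")
    return node


def genes_in(node: Node | None) -> set[str]:
    if node is None:
        return set()
    kind = node[0]
    if kind == "gene":
        return {node[1]}
    return set().union(*(genes_in(child) for child in node[1]))


def eval_bool(node: Node | None, present: Callable[[str], bool]) -> bool:
    """Evaluate gene presence: is the reaction still catalysable?

    An empty rule (``None``) evaluates True: reactions without gene
    annotation are never knocked out.
    """
    if node is None:
        return True
    kind = node[0]
    if kind == "gene":
        return bool(present(node[1]))
    if kind == "and":
        return all(eval_bool(child, present) for child in node[1])
    return any(eval_bool(child, present) for child in node[1])


def eval_direction(node: Node | None, direction: Mapping[str, int]) -> int:
    """Propagate per-gene regulation directions through a GPR rule.

    ``direction`` maps gene id -> -1 (down), 0 (unchanged) or +1 (up);
    unmapped genes count as unchanged.  AND returns the minimum of its
    branches (most restrictive: down dominates), OR the maximum (least
    restrictive: up dominates).  Empty rules give 0.
    """
    if node is None:
        return 0
    kind = node[0]
    if kind == "gene":
        return int(direction.get(node[1], 0))
    values = [eval_direction(child, direction) for child in node[1]]
    return min(values) if kind == "and" else max(values)
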