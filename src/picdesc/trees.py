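"""Minimal bracketed constituency trees (Penn-Treebank style strings)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

__all__ = ["TreeNode", "ParseFormatError", "parse_tree"]


class ParseFormatError(ValueError):
    """Unbalanced or malformed bracketed parse string."""


@dataclass(frozen=True)
class TreeNode:
    label: str
    children: tuple["TreeNode", ...] = ()
    leaf: str | None = None  # terminal word for preterminal nodes

    @property
    def is_preterminal(self) -> bool:
        return self.leaf is not None

    def walk(self) -> Iterator["TreeNode"]:
        """All nodes, depth-first, self first."""
        yield self
        for child in self.children:
            yield from child.walk()

    def leaves(self) -> list[str]:
        if self.leaf is not None:
            return [self.leaf]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def __str__(self) -> str:
        if self.leaf is not None:
            return f"({self.label} {self.leaf})"
        return "(" + self.label + " " + " ".join(str(c) for c in self.children) + ")"


def _tokenize(text: str) -> list[str]:
    return text.replace("(", " ( ").replace(")", " ) ").split()


def parse_tree(text: str) -> TreeNode:
    """Parse a bracketed constituency string like
    ``(S (NP (DT the) (NN boy)) (VP (VBZ runs)))``."""
    tokens = _tokenize(text)
    if not tokens:
        raise ParseFormatError("empty parse string")
    pos = 0

    def read_node() -> TreeNode:
        nonlocal pos
        if tokens[pos] != "(":
            raise ParseFormatError(f"expected '(' at token {pos}: {tokens[pos]!r}")
        pos += 1
        if pos >= len(tokens) or tokens[pos] in "()":
            raise ParseFormatError(f"missing node label at token {pos}")
        label = tokens[pos]
        pos += 1
        children: list[TreeNode] = []
        words: list[str] = []
        while pos < len(tokens) and tokens[pos] != ")":
            if tokens[pos] == "(":
                children.append(read_node())
            else:
                words.append(tokens[pos])
                pos += 1
        if pos >= len(tokens):
            raise ParseFormatError("unbalanced brackets: unexpected end of string")
        pos += 1  # consume ')'
        if children and words:
            raise ParseFormatError(f"node {label!r} mixes terminals and subtrees")
        if words:
            return TreeNode(label=label, leaf=" ".join(words))
        return TreeNode(label=label, children=tuple(children))

    root = read_node()
    if pos != len(tokens):
        raise ParseFormatError("unbalanced brackets: trailing tokens after root")
    return root
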