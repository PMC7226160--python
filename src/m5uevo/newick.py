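"""Newick parsing and writing for rooted, internally labeled species trees.

A hand-rolled recursive-descent parser is used instead of a library wrapper
so that parse errors carry exact character positions and so that
``parse -> write -> parse`` is stable on the canonical form (children in
input order, labels and branch lengths preserved verbatim).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional


class NewickError(ValueError):
    """Malformed newick input; ``position`` is a 0-based character offset."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass
class TreeNode:
    label: Optional[str] = None
    branch_length: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None
    group_tag: Optional[str] = None
    mycoides_cluster: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]


class SpeciesTree:
    """Rooted tree with unique leaf labels and unique internal labels."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._index: dict[str, TreeNode] = {}
        for node in root.preorder():
            if node.label is None:
                continue
            if node.label in self._index:
                raise NewickError(f"duplicate node label {node.label!r}", 0)
            self._index[node.label] = node

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def node(self, label: str) -> TreeNode:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"no node labeled {label!r} in tree") from None

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    @property
    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    def mrca(self, labels) -> TreeNode:
        """Most recent common ancestor of the given node labels."""
        labels = list(labels)
        if not labels:
            raise ValueError("mrca of empty label set")
        paths = []
        for lab in labels:
            node = self.node(lab)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        mrca = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            candidate = paths[0][depth]
            if all(p[depth] is candidate for p in paths):
                mrca = candidate
            else:
                break
        return mrca

    def leaf_set_under(self, label: str) -> frozenset[str]:
        return frozenset(n.label for n in self.node(label).leaves())


def _parse_label(text: str, pos: int) -> tuple[Optional[str], int]:
    start = pos
    while pos < len(text) and text[pos] not in "(),:;":
        pos += 1
    label = text[start:pos].strip()
    return (label or None, pos)


def _parse_branch_length(text: str, pos: int) -> tuple[Optional[float], int]:
    if pos >= len(text) or text[pos] != ":":
        return None, pos
    pos += 1
    start = pos
    while pos < len(text) and text[pos] not in "(),;":
        pos += 1
    raw = text[start:pos].strip()
    try:
        value = float(raw)
    except ValueError:
        raise NewickError(f"bad branch length {raw!r}", start)
    if value < 0:
        raise NewickError(f"negative branch length {raw!r}", start)
    return value, pos


def _parse_clade(text: str, pos: int) -> tuple[TreeNode, int]:
    node = TreeNode()
    if pos < len(text) and text[pos] == "(":
        pos += 1
        while True:
            child, pos = _parse_clade(text, pos)
            child.parent = node
            node.children.append(child)
            if pos >= len(text):
                raise NewickError("unbalanced parentheses: unexpected end", pos)
            if text[pos] == ",":
                pos += 1
                continue
            if text[pos] == ")":
                pos += 1
                break
            raise NewickError(f"unexpected character {text[pos]!r}", pos)
    node.label, pos = _parse_label(text, pos)
    node.branch_length, pos = _parse_branch_length(text, pos)
    return node, pos


def parse_newick(text: str) -> SpeciesTree:
    """Parse a newick string into a :class:`SpeciesTree`.

    Internal node labels and branch lengths are optional and preserved.
    Raises :class:`NewickError` naming the offending position on malformed
    input or duplicate labels.
    """
    stripped = text.strip()
    if not stripped:
        raise NewickError("empty newick string", 0)
    root, pos = _parse_clade(stripped, 0)
    if pos >= len(stripped) or stripped[pos] != ";":
        raise NewickError("expected ';' terminator", pos)
    if stripped[pos + 1:].strip():
        raise NewickError("trailing content after ';'", pos + 1)
    tree = SpeciesTree(root)
    leaf_labels = [n.label for n in root.leaves()]
    for leaf in root.leaves():
        if leaf.label is None:
            raise NewickError("unlabeled leaf", 0)
    if len(set(leaf_labels)) != len(leaf_labels):
        dupes = sorted({l for l in leaf_labels if leaf_labels.count(l) > 1})
        raise NewickError(f"duplicate leaf labels {dupes}", 0)
    return tree


def _write_clade(node: TreeNode) -> str:
    parts = ""
    if node.children:
        parts = "(" + ",".join(_write_clade(c) for c in node.children) + ")"
    parts += node.label or ""
    if node.branch_length is not None:
        length = repr(node.branch_length)
        if length.endswith(".0"):
            length = length[:-2]
        parts += f":{length}"
    return parts


def write_newick(tree: SpeciesTree) -> str:
    return _write_clade(tree.root) + ";"
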