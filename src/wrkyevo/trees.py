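"""Rooted phylogenetic trees and Newick I/O.

Trees are rooted, with optional branch lengths (any non-negative unit:
substitutions/site for gene trees, Myr for dated species trees) and optional
support values on internal nodes.  Support values are carried as internal
node labels in Newick, on a 0-100 scale (bootstrap percentages).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Optional


class NewickError(ValueError):
    """Raised for malformed Newick input."""


@dataclass
class TreeNode:
    label: str = ""
    children: list["TreeNode"] = field(default_factory=list)
    branch_length: Optional[float] = None
    support: Optional[float] = None

    # -- structure ---------------------------------------------------------

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def copy(self) -> "TreeNode":
        return TreeNode(
            label=self.label,
            children=[c.copy() for c in self.children],
            branch_length=self.branch_length,
            support=self.support,
        )

    def find(self, label: str) -> Optional["TreeNode"]:
        for n in self.postorder():
            if n.label == label:
                return n
        return None

    # -- derived maps ------------------------------------------------------

    def parent_map(self) -> dict[int, "TreeNode"]:
        """id(node) -> parent node (root absent)."""
        parents: dict[int, TreeNode] = {}
        for n in self.preorder():
            for c in n.children:
                parents[id(c)] = n
        return parents

    def depths(self) -> dict[int, int]:
        """id(node) -> edge count from root."""
        out = {id(self): 0}
        for n in self.preorder():
            for c in n.children:
                out[id(c)] = out[id(n)] + 1
        return out

    def node_ages(self) -> dict[int, float]:
        """For ultrametric dated trees: id(node) -> age (time before present).

        Computed as tree height minus distance from root via branch lengths.
        """
        dist = {id(self): 0.0}
        for n in self.preorder():
            for c in n.children:
                dist[id(c)] = dist[id(n)] + (c.branch_length or 0.0)
        height = max(dist[id(l)] for l in self.leaves())
        return {k: height - v for k, v in dist.items()}

    def total_branch_length(self) -> float:
        return sum(n.branch_length or 0.0 for n in self.postorder() if n is not self)

    # -- LCA ---------------------------------------------------------------

    def lca_table(self) -> "LcaTable":
        return LcaTable(self)

    def __repr__(self) -> str:  # keeps pytest diffs readable
        return f"TreeNode({to_newick_string(self)!r})"


class LcaTable:
    """Constant-depth-walk LCA queries over a fixed rooted tree."""

    def __init__(self, root: TreeNode):
        self.root = root
        self.parent = root.parent_map()
        self.depth = root.depths()

    def lca(self, a: TreeNode, b: TreeNode) -> TreeNode:
        da, db = self.depth[id(a)], self.depth[id(b)]
        while da > db:
            a = self.parent[id(a)]
            da -= 1
        while db > da:
            b = self.parent[id(b)]
            db -= 1
        while a is not b:
            a = self.parent[id(a)]
            b = self.parent[id(b)]
        return a

    def is_ancestor_or_self(self, anc: TreeNode, node: TreeNode) -> bool:
        return self.lca(anc, node) is anc

    def edge_distance(self, anc: TreeNode, node: TreeNode) -> int:
        """Edges from ancestor down to node (must be ancestor-or-self)."""
        d = self.depth[id(node)] - self.depth[id(anc)]
        if d < 0 or self.lca(anc, node) is not anc:
            raise ValueError("edge_distance requires an ancestor-descendant pair")
        return d


# ---------------------------------------------------------------------------
# Newick parsing / writing
# ---------------------------------------------------------------------------

_SPECIALS = set("(),:;")


def _parse_label(s: str, i: int) -> tuple[str, int]:
    j = i
    while j < len(s) and s[j] not in _SPECIALS and not s[j].isspace():
        j += 1
    return s[i:j], j


def _skip_ws(s: str, i: int) -> int:
    while i < len(s) and s[i].isspace():
        i += 1
    return i


def parse_newick(text: str) -> TreeNode:
    """Parse a single Newick tree.

    Internal node labels that are plain numbers in [0, 100] are interpreted
    as bootstrap support values (the convention used throughout this
    package); any other internal label is kept as a name.
    """
    s = text.strip()
    if not s:
        raise NewickError("empty Newick input")

    def parse_clade(i: int) -> tuple[TreeNode, int]:
        i = _skip_ws(s, i)
        node = TreeNode()
        if i < len(s) and s[i] == "(":
            i += 1
            while True:
                child, i = parse_clade(i)
                node.children.append(child)
                i = _skip_ws(s, i)
                if i >= len(s):
                    raise NewickError("unbalanced parentheses: unexpected end of input")
                if s[i] == ",":
                    i += 1
                    continue
                if s[i] == ")":
                    i += 1
                    break
                raise NewickError(f"unexpected character {s[i]!r} at position {i}")
        i = _skip_ws(s, i)
        label, i = _parse_label(s, i)
        if label:
            if node.children:
                try:
                    val = float(label)
                except ValueError:
                    node.label = label
                else:
                    if 0.0 <= val <= 100.0:
                        node.support = val
                    else:
                        node.label = label
            else:
                node.label = label
        i = _skip_ws(s, i)
        if i < len(s) and s[i] == ":":
            i += 1
            raw, i = _parse_label(s, i)
            try:
                node.branch_length = float(raw)
            except ValueError:
                raise NewickError(f"bad branch length {raw!r}") from None
        return node, i

    root, i = parse_clade(0)
    i = _skip_ws(s, i)
    if i >= len(s) or s[i] != ";":
        raise NewickError("unbalanced parentheses or missing terminal ';'")
    if s[i + 1 :].strip():
        raise NewickError("trailing characters after ';'")
    leaf_labels = root.leaf_labels()
    if len(set(leaf_labels)) != len(leaf_labels):
        raise NewickError("duplicate leaf labels")
    return root


def _fmt_float(x: float) -> str:
    x = float(x)
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(round(x, 10))


def to_newick_string(node: TreeNode) -> str:
    buf = io.StringIO()

    def emit(n: TreeNode) -> None:
        if n.children:
            buf.write("(")
            for k, c in enumerate(n.children):
                if k:
                    buf.write(",")
                emit(c)
            buf.write(")")
            if n.label:
                buf.write(n.label)
            elif n.support is not None:
                buf.write(_fmt_float(n.support))
        else:
            buf.write(n.label)
        if n.branch_length is not None:
            buf.write(":" + _fmt_float(n.branch_length))

    emit(node)
    buf.write(";")
    return buf.getvalue()


def read_newick(path) -> TreeNode:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick_string(tree) + "\n")
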