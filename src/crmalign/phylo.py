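"""Rooted binary phylogenies with branch lengths.

Trees are inputs (Newick, parsed with dendropy); this module converts them to
a minimal internal node structure suited to the progressive up/down passes:
every node knows its parent, children, branch length to its parent, and a
stable name (internal nodes are auto-named ``node<k>`` in post-order if the
Newick string leaves them unlabeled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy

__all__ = ["TreeNode", "Phylogeny", "TreeFormatError", "read_newick", "parse_newick"]


class TreeFormatError(ValueError):
    """Unusable tree input (polytomy, missing branch length, ...)."""


@dataclass(eq=False)
class TreeNode:
    name: str
    length: float = 0.0  # branch length to parent; 0 at the root
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):
        return f"TreeNode({self.name!r})"


class Phylogeny:
    """A rooted, strictly binary tree with positive branch lengths."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()
        self.nodes = {n.name: n for n in self.postorder()}

    def _validate(self):
        seen = set()
        for node in self.postorder():
            if node.children and len(node.children) != 2:
                raise TreeFormatError(
                    f"node {node.name!r} has {len(node.children)} children; "
                    "only strictly binary trees are supported"
                )
            if node.parent is not None and not node.length > 0:
                raise TreeFormatError(
                    f"node {node.name!r} has non-positive branch length "
                    f"{node.length}"
                )
            if node.is_leaf:
                if node.name in seen:
                    raise TreeFormatError(f"duplicate leaf name {node.name!r}")
                seen.add(node.name)

    def postorder(self):
        out = []

        def walk(n):
            for c in n.children:
                walk(c)
            out.append(n)

        walk(self.root)
        return out

    def preorder(self):
        out = []

        def walk(n):
            out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.parent is not None)

    def mrca(self, names) -> TreeNode:
        names = set(names)
        if not names:
            raise ValueError("mrca of an empty taxon set")
        below = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = {node.name} & names
            else:
                below[node] = set().union(*(below[c] for c in node.children))
            if below[node] == names:
                return node
        raise ValueError(f"taxa {names} not all present in tree")

    def scaled(self, factor: float) -> "Phylogeny":
        """A copy with all branch lengths multiplied by ``factor``."""

        def copy(n, parent):
            m = TreeNode(n.name, n.length * factor, parent=parent)
            m.children = [copy(c, m) for c in n.children]
            return m

        return Phylogeny(copy(self.root, None))

    def to_newick(self) -> str:
        def fmt(n):
            if n.is_leaf:
                core = n.name
            else:
                core = "(" + ",".join(fmt(c) for c in n.children) + ")" + (
                    n.name if not n.name.startswith("node") else ""
                )
            if n.parent is None:
                return core
            return f"{core}:{n.length:.10g}"

        return fmt(self.root) + ";"


def parse_newick(newick: str) -> Phylogeny:
    """Parse a single rooted Newick tree with branch lengths."""
    try:
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:
        raise TreeFormatError(f"cannot parse Newick input: {exc}") from exc

    counter = [0]

    def convert(dnode, parent):
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        if label is None:
            label = f"node{counter[0]}"
            counter[0] += 1
        length = dnode.edge.length
        if parent is not None and length is None:
            raise TreeFormatError(f"branch above {label!r} has no length")
        node = TreeNode(label.replace(" ", "_"), float(length or 0.0), parent=parent)
        node.children = [convert(c, node) for c in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node, None)
    # dendropy may wrap a single-child root; collapse it
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = 0.0
    return Phylogeny(root)


def read_newick(path) -> Phylogeny:
    return parse_newick(Path(path).read_text())
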