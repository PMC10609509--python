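"""Lightweight phylogeny container used across the package.

Trees are held as plain node objects (unrooted trees are represented with a
basal trifurcation, rooted inputs with a degree-2 root are handled
transparently) and serialised through Newick. Bipartitions are computed as
leaf bitmasks over the sorted taxon labels; the canonical orientation of a
split is the side containing the lexicographically smallest label.
"""

from __future__ import annotations

from typing import Iterator

import dendropy


class Node:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Phylogeny:
    """A tree with branch lengths; the source of canonical bipartitions."""

    def __init__(self, root: Node):
        self.root = root

    # -- construction / IO --------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(_from_dendropy(dtree.seed_node))

    @classmethod
    def read(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self, include_lengths: bool = True) -> str:
        return _write_newick(self.root, include_lengths) + ";"

    def write(self, path, include_lengths: bool = True) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(include_lengths) + "\n")

    # -- traversal ----------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def taxa(self) -> list[str]:
        return sorted(n.name for n in self.leaves())

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.postorder() if n.is_leaf)

    def edges(self) -> list[Node]:
        """Every node below an edge (i.e. all non-root nodes)."""
        return [n for n in self.postorder() if n.parent is not None]

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.edges())

    def copy(self) -> "Phylogeny":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Phylogeny(clone(self.root))

    # -- bipartitions -------------------------------------------------------
    def split_masks(self) -> dict[int, float]:
        """Canonical non-trivial split bitmasks -> branch length.

        Leaf bit i corresponds to the i-th taxon in sorted label order; each
        mask includes bit 0. A degree-2 root contributes a single merged
        edge (its two child edges describe the same split; lengths are
        summed).
        """
        taxa = self.taxa
        index = {name: i for i, name in enumerate(taxa)}
        n = len(taxa)
        full = (1 << n) - 1
        masks: dict[Node, int] = {}
        splits: dict[int, float] = {}
        root_degree2 = len(self.root.children) == 2
        for node in self.postorder():
            if node.is_leaf:
                masks[node] = 1 << index[node.name]
            else:
                m = 0
                for child in node.children:
                    m |= masks[child]
                masks[node] = m
        for node in self.postorder():
            if node.parent is None:
                continue
            m = masks[node]
            size = m.bit_count()
            if size < 2 or size > n - 2:
                continue
            canonical = m if (m & 1) else (full ^ m)
            length = node.length or 0.0
            if root_degree2 and node.parent is self.root:
                sibling = next(c for c in self.root.children if c is not node)
                if canonical in splits:
                    continue  # already recorded via the sibling
                length = (node.length or 0.0) + (sibling.length or 0.0)
            splits[canonical] = length
        return splits


def _from_dendropy(dnode) -> Node:
    name = None
    if dnode.taxon is not None:
        name = dnode.taxon.label
    elif dnode.label:
        name = dnode.label
    node = Node(name, dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def _write_newick(node: Node, include_lengths: bool) -> str:
    if node.is_leaf:
        out = node.name or ""
    else:
        out = "(" + ",".join(_write_newick(c, include_lengths) for c in node.children) + ")"
        if node.name:
            out += node.name
    if include_lengths and node.length is not None:
        out += f":{node.length:.10g}"
    return out
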