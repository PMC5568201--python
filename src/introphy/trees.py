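"""Minimal rooted-tree container shared by the simulator, NJ and dating.

The calibration experiments build on the order of 10^5 small gene trees, so
the hot paths use this slotted node structure; Newick parsing/writing at
file boundaries goes through dendropy, which is also the comparison point
in the cross-check tests.
"""

from __future__ import annotations

from typing import Iterator

import dendropy


class Node:
    __slots__ = ("name", "children", "parent", "length", "age", "support")

    def __init__(self, name=None, length=0.0):
        self.name = name
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length  # edge length to parent
        self.age = None  # filled by dating / simulation (time units)
        self.support = None  # bootstrap support of the edge above (0-100)

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.name or 'internal'}>"


class Tree:
    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_edges(self) -> list[Node]:
        """Nodes whose edge to the parent is internal (non-root, non-leaf)."""
        return [
            n for n in self.preorder()
            if n.parent is not None and not n.is_leaf
        ]

    # -- derived quantities ------------------------------------------------
    def set_ages_from_lengths(self) -> None:
        """Node ages assuming an ultrametric tree with tip age 0."""
        depth = {self.root: 0.0}
        maxd = 0.0
        for n in self.preorder():
            if n.parent is not None:
                depth[n] = depth[n.parent] + n.length
            if n.is_leaf:
                maxd = max(maxd, depth[n])
        for n in self.preorder():
            n.age = maxd - depth[n]

    def set_lengths_from_ages(self) -> None:
        for n in self.preorder():
            if n.parent is not None:
                n.length = n.parent.age - n.age

    def pair_mrca_ages(self) -> dict[frozenset, float]:
        """Age of the MRCA for every leaf pair (requires node.age set)."""
        below: dict[Node, list[str]] = {}
        ages: dict[frozenset, float] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[n] = [n.name]
                continue
            kids = [below[c] for c in n.children]
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    for a in kids[i]:
                        for b in kids[j]:
                            ages[frozenset((a, b))] = n.age
            below[n] = [x for k in kids for x in k]
        return ages

    def bipartitions(self) -> set[frozenset]:
        """Unrooted non-trivial splits, canonicalized to exclude a reference leaf."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out: set[frozenset] = set()
        below: dict[Node, frozenset] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[n] = frozenset((n.name,))
                continue
            side = frozenset().union(*(below[c] for c in n.children))
            below[n] = side
            if n.parent is None:
                continue
            if ref in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return out

    def sister_pair(self, names: tuple[str, str, str]) -> frozenset:
        """Which of three leaves are sisters (most recent MRCA), by ages."""
        ages = self.pair_mrca_ages()
        a, b, c = names
        pairs = [frozenset((a, b)), frozenset((a, c)), frozenset((b, c))]
        return min(pairs, key=lambda p: ages[p])

    # -- IO ----------------------------------------------------------------
    def to_newick(self, support_as_label: bool = False) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                return f"{n.name}:{n.length:.10g}"
            inner = ",".join(fmt(c) for c in n.children)
            label = ""
            if support_as_label and n.support is not None:
                label = f"{n.support:g}"
            elif n.name:
                label = n.name
            if n.parent is None:
                return f"({inner}){label}"
            return f"({inner}){label}:{n.length:.10g}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Tree":
        def conv(dn) -> Node:
            name = dn.taxon.label if dn.taxon is not None else dn.label
            n = Node(name=name, length=dn.edge.length or 0.0)
            for c in dn.child_nodes():
                n.add_child(conv(c))
            return n

        return cls(conv(dtree.seed_node))

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick")

    def copy(self) -> "Tree":
        def conv(n: Node) -> Node:
            m = Node(name=n.name, length=n.length)
            m.age = n.age
            m.support = n.support
            for c in n.children:
                m.add_child(conv(c))
            return m

        return Tree(conv(self.root))


def write_newick(trees: list[Tree], path, support_as_label: bool = False) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick(support_as_label=support_as_label) + "\n")


def read_newick(path) -> list[Tree]:
    with open(path) as fh:
        return [Tree.from_newick(line) for line in fh if line.strip()]
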