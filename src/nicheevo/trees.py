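"""Ultrametric time-calibrated trees.

A minimal rooted-tree container in which every node carries an age (time
before present, in Ma). Branch lengths are implied: parent age minus child
age. Tips sit at age 0, so the tree is ultrametric by construction, which is
the regime in which Brownian-motion ancestral reconstruction is applied
downstream. Newick serialisation round-trips through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import dendropy
import numpy as np


@dataclass
class TreeNode:
    age: float
    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child


class UltrametricTree:
    """Rooted tree with node ages; tips at age ~0.

    Internal nodes receive a stable name: the sorted tip labels of their
    clade joined by '|'.
    """

    def __init__(self, root: TreeNode, age_tolerance: float = 1e-6):
        self.root = root
        self.age_tolerance = age_tolerance
        self._name_internal_nodes()
        self.validate()

    # -- construction / naming ------------------------------------------------

    def _name_internal_nodes(self) -> None:
        def tips_below(node: TreeNode) -> list[str]:
            if node.is_tip:
                if node.label is None:
                    raise ValueError("tip without a label")
                return [node.label]
            labels = []
            for c in node.children:
                labels.extend(tips_below(c))
            if node.label is None:
                node.label = "|".join(sorted(labels))
            return labels

        tips_below(self.root)

    # -- traversal ------------------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips]

    @property
    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_tip]

    @property
    def root_age(self) -> float:
        return self.root.age

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        for node in self.preorder():
            for child in node.children:
                if not child.age < node.age:
                    raise ValueError(
                        f"node age ordering violated: parent {node.label} age {node.age} "
                        f"<= child {child.label} age {child.age}"
                    )
        tol = max(self.age_tolerance, self.age_tolerance * abs(self.root.age))
        for tip in self.tips:
            if abs(tip.age) > tol:
                raise ValueError(f"tip {tip.label} has nonzero age {tip.age} (not ultrametric)")

    # -- covariance machinery -------------------------------------------------

    def mrca_age(self, label_a: str, label_b: str) -> float:
        path: dict[int, TreeNode] = {}
        node = self._tip(label_a)
        while node is not None:
            path[id(node)] = node
            node = node.parent
        node = self._tip(label_b)
        while node is not None:
            if id(node) in path:
                return node.age
            node = node.parent
        raise ValueError("tips do not share a root")

    def _tip(self, label: str) -> TreeNode:
        for t in self.tips:
            if t.label == label:
                return t
        raise KeyError(f"no tip labelled {label!r}")

    def vcv(self, order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Brownian-motion covariance: shared path length from the root.

        V[i, j] = root_age - age(MRCA(i, j)); V[i, i] = root-to-tip depth.
        """
        labels = order if order is not None else self.tip_labels
        n = len(labels)
        v = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                v[i, j] = v[j, i] = self.root.age - self.mrca_age(labels[i], labels[j])
        return v, labels

    def node_distances(self, node: TreeNode) -> dict[str, float]:
        """Path length from `node` to every tip, through the tree edges."""
        dist: dict[int, float] = {id(node): 0.0}
        out: dict[str, float] = {}
        # walk the tree as an undirected graph
        stack = [(node, None)]
        while stack:
            cur, came_from = stack.pop()
            neighbours = list(cur.children)
            if cur.parent is not None:
                neighbours.append(cur.parent)
            for nb in neighbours:
                if came_from is not None and nb is came_from:
                    continue
                edge = abs(nb.age - cur.age)
                dist[id(nb)] = dist[id(cur)] + edge
                if nb.is_tip:
                    out[nb.label] = dist[id(nb)]
                stack.append((nb, cur))
        if node.is_tip:
            out[node.label] = 0.0
        return out

    def rerooted_vcv(self, node: TreeNode, order: list[str]) -> np.ndarray:
        """Covariance of tip values about `node` treated as the root.

        V'[i, j] = (d(node, i) + d(node, j) - d(i, j)) / 2, path lengths
        measured along tree edges; exact for BM regardless of root position.
        """
        d_node = self.node_distances(node)
        n = len(order)
        tip_d = np.empty((n, n))
        for i, a in enumerate(order):
            d_a = self.node_distances(self._tip(a))
            for j, b in enumerate(order):
                tip_d[i, j] = d_a[b]
        di = np.array([d_node[t] for t in order])
        return (di[:, None] + di[None, :] - tip_d) / 2.0

    # -- serialisation --------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: TreeNode, parent_age: float | None) -> str:
            if node.is_tip:
                core = node.label
            else:
                core = "(" + ",".join(fmt(c, node.age) for c in node.children) + ")"
            if parent_age is None:
                return core
            return f"{core}:{parent_age - node.age:.10g}"

        return fmt(self.root, None) + ";"

    @classmethod
    def from_newick(cls, newick: str, age_tolerance: float = 1e-6) -> "UltrametricTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        droot = dtree.seed_node
        depths: dict[dendropy.Node, float] = {droot: 0.0}
        for dnode in dtree.preorder_node_iter():
            if dnode is droot:
                continue
            depths[dnode] = depths[dnode.parent_node] + (dnode.edge.length or 0.0)
        height = max(depths[leaf] for leaf in dtree.leaf_node_iter())

        def convert(dnode: dendropy.Node) -> TreeNode:
            age = height - depths[dnode]
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = TreeNode(age=age, label=label)
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            if node.is_tip:
                node.age = 0.0 if abs(age) <= max(age_tolerance, age_tolerance * height) else age
            return node

        return cls(convert(droot), age_tolerance=age_tolerance)
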