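"""Rooted binary phylogenetic trees and target lineages.

Trees are stored in a flat array representation (parent pointers, child
lists, branch lengths, post-order) that the likelihood engine and the
trainer index directly.  Newick parsing/writing is delegated to dendropy;
only strictly binary rooted trees with branch lengths on every non-root
edge are accepted.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "TargetLineage",
    "read_newick",
    "write_newick",
    "extract_lineage",
    "restrict_to_leaves",
]


class TreeError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class PhyloTree:
    """Rooted binary tree in flat-array form.

    ``parent[n]`` is the parent index (-1 for the root), ``children[n]`` a
    tuple of child indices (empty for leaves), ``lengths[n]`` the branch
    length from ``n`` to its parent (0.0 at the root), ``names[n]`` the leaf
    name or an optional internal label (may be ``None``).
    """

    parent: np.ndarray
    children: tuple
    lengths: np.ndarray
    names: tuple

    def __post_init__(self):
        for n, kids in enumerate(self.children):
            if len(kids) not in (0, 2):
                raise TreeError(
                    f"node {self.names[n] or n} is multifurcating/unary; "
                    "only binary trees are supported"
                )
        leaf_names = [self.names[n] for n in self.leaf_indices()]
        if any(name is None for name in leaf_names):
            raise TreeError("every leaf must be named")
        if len(set(leaf_names)) != len(leaf_names):
            raise TreeError("leaf names must be unique")
        if np.any(self.lengths < 0):
            raise TreeError("branch lengths must be non-negative")

    # -- basic structure ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def is_leaf(self, n: int) -> bool:
        return len(self.children[n]) == 0

    def leaf_indices(self) -> list[int]:
        return [n for n in range(self.n_nodes) if self.is_leaf(n)]

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[n] for n in self.leaf_indices()]

    def leaf_index(self, name: str) -> int:
        for n in self.leaf_indices():
            if self.names[n] == name:
                return n
        raise KeyError(f"unknown leaf: {name!r}")

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(self.children[n])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def sibling(self, n: int) -> int:
        p = int(self.parent[n])
        if p < 0:
            raise TreeError("the root has no sibling")
        a, b = self.children[p]
        return b if a == n else a

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:
            raise TreeError(f"cannot parse newick: {exc}") from exc
        dnodes = list(dtree.preorder_node_iter())
        index = {id(dn): i for i, dn in enumerate(dnodes)}
        parent = np.full(len(dnodes), -1, dtype=int)
        lengths = np.zeros(len(dnodes))
        children: list[tuple] = [() for _ in dnodes]
        names: list[str | None] = [None] * len(dnodes)
        for i, dn in enumerate(dnodes):
            kids = dn.child_nodes()
            children[i] = tuple(index[id(k)] for k in kids)
            if dn.taxon is not None:
                names[i] = dn.taxon.label
            elif dn.label:
                names[i] = dn.label
            if dn.parent_node is not None:
                parent[i] = index[id(dn.parent_node)]
                if dn.edge.length is None:
                    raise TreeError(
                        f"missing branch length above node {names[i] or i}"
                    )
                lengths[i] = float(dn.edge.length)
        return cls(parent=parent, children=tuple(children), lengths=lengths, names=tuple(names))

    def to_newick(self) -> str:
        def fmt(n: int) -> str:
            if self.is_leaf(n):
                label = self.names[n]
            else:
                a, b = self.children[n]
                label = f"({fmt(a)},{fmt(b)})" + (self.names[n] or "")
            if int(self.parent[n]) < 0:
                return label
            return f"{label}:{self.lengths[n]:.10g}"

        return fmt(self.root) + ";"


def read_newick(path) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text())


def write_newick(tree: PhyloTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


@dataclasses.dataclass(frozen=True)
class TargetLineage:
    """The leaf-to-root path of the target species.

    ``nodes[k]`` is the k-th node on the path (``nodes[0]`` the target leaf,
    ``nodes[M]`` the root); ``siblings[k]`` (for k >= 1) is the sibling of
    ``nodes[k-1]``; ``edge_lengths[k]`` the length of the path edge ending
    at ``nodes[k]``; ``taus[k]`` the cumulative path length from the leaf to
    ``nodes[k]`` and ``fractions[k] = taus[k] / tbar``.
    """

    target: str
    nodes: tuple
    siblings: tuple
    edge_lengths: np.ndarray
    taus: np.ndarray
    fractions: np.ndarray
    tbar: float

    @property
    def M(self) -> int:
        return len(self.nodes) - 1


def extract_lineage(tree: PhyloTree, target: str) -> TargetLineage:
    leaf = tree.leaf_index(target)
    nodes = [leaf]
    while int(tree.parent[nodes[-1]]) >= 0:
        nodes.append(int(tree.parent[nodes[-1]]))
    siblings = [tree.sibling(n) for n in nodes[:-1]]
    edge_lengths = np.array([tree.lengths[n] for n in nodes[:-1]])
    taus = np.concatenate([[0.0], np.cumsum(edge_lengths)])
    tbar = float(taus[-1])
    # a zero-length lineage is representable (fractions degenerate); the
    # estimation engine rejects it, but simulation bookkeeping tolerates it
    fractions = taus / tbar if tbar > 0 else np.linspace(0.0, 1.0, len(taus))
    return TargetLineage(
        target=target,
        nodes=tuple(nodes),
        siblings=tuple(siblings),
        edge_lengths=edge_lengths,
        taus=taus,
        fractions=fractions,
        tbar=tbar,
    )


def restrict_to_leaves(tree: PhyloTree, keep: set[str] | list[str]) -> PhyloTree:
    """Prune the tree down to ``keep``, suppressing unary nodes.

    Branch lengths of suppressed nodes are summed onto the retained child.
    If one side of the root is removed entirely, the surviving child becomes
    the new root (its stem branch is dropped).
    """
    keep = set(keep)
    unknown = keep - set(tree.leaf_names)
    if unknown:
        raise KeyError(f"unknown leaves: {sorted(unknown)}")
    if not keep:
        raise TreeError("cannot restrict to an empty leaf set")

    # build nested (name, length, children) structure of the kept subtree
    def build(n: int):
        if tree.is_leaf(n):
            if tree.names[n] in keep:
                return {"name": tree.names[n], "length": float(tree.lengths[n]), "kids": []}
            return None
        kids = [build(c) for c in tree.children[n]]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kid = kids[0]
            kid = dict(kid)
            kid["length"] += float(tree.lengths[n])
            return kid
        return {"name": tree.names[n], "length": float(tree.lengths[n]), "kids": kids}

    top = build(tree.root)
    if top is None:
        raise TreeError("no kept leaves")
    top = dict(top)
    top["length"] = 0.0

    parent: list[int] = []
    lengths: list[float] = []
    children: list[list[int]] = []
    names: list[str | None] = []

    def emit(node, par: int) -> int:
        i = len(parent)
        parent.append(par)
        lengths.append(node["length"])
        children.append([])
        names.append(node["name"])
        if par >= 0:
            children[par].append(i)
        for kid in node["kids"]:
            emit(kid, i)
        return i

    emit(top, -1)
    return PhyloTree(
        parent=np.array(parent, dtype=int),
        children=tuple(tuple(c) for c in children),
        lengths=np.array(lengths),
        names=tuple(names),
    )
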