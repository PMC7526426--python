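"""UPGMA guide tree over the structure distance matrix.

The tree is stored as a rooted binary tree: leaves carry indices
0..N-1 (the structure indices), internal nodes are numbered N..2N-2 in
merge order, so whether a node is a leaf is readable from its index alone.
Average-linkage (UPGMA) agglomeration yields an ultrametric tree; node
heights are half the merge distance, so all branch lengths are
non-negative and all root-to-leaf paths have equal length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import DistanceMatrix

__all__ = [
    "TreeNode",
    "GuideTree",
    "upgma",
    "tie_break",
    "post_order",
    "node_depth",
    "theoretical_balanced_speedup",
    "to_newick",
    "tree_table_tsv",
]


class TreeError(ValueError):
    pass


@dataclass
class TreeNode:
    index: int
    height: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    members: frozenset[int] = field(default_factory=frozenset)

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None


@dataclass
class GuideTree:
    root: TreeNode
    n_leaves: int

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    def nodes_by_index(self) -> dict[int, TreeNode]:
        return {node.index: node for node in _iter_nodes(self.root)}


def _iter_nodes(root: TreeNode):
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        if node.right is not None:
            stack.append(node.right)
        if node.left is not None:
            stack.append(node.left)


def tie_break(candidates) -> tuple[int, int]:
    """Choose among equally-minimal cluster pairs: each pair is normalized
    to (smaller index, larger index) and the lexicographically smallest
    pair wins. Pinned so the merge order is deterministic."""
    normalized = [(min(a, b), max(a, b)) for a, b in candidates]
    if not normalized:
        raise TreeError("no candidates to break ties among")
    return min(normalized)


def upgma(D: DistanceMatrix) -> GuideTree:
    """Average-linkage agglomeration of a validated distance matrix.

    Repeatedly merges the cluster pair at minimal distance (ties broken by
    :func:`tie_break` on cluster node indices); the new node's height is
    half the merge distance and its distance to every other cluster is the
    size-weighted average of its children's distances (classic UPGMA
    update). Internal node indices are assigned N, N+1, ... in merge
    order, with the smaller-index cluster as left child.
    """
    n = D.n
    if n < 2:
        raise TreeError("UPGMA needs at least 2 items")

    nodes: dict[int, TreeNode] = {
        i: TreeNode(index=i, height=0.0, members=frozenset([i])) for i in range(n)
    }
    # current inter-cluster distances, keyed by (smaller, larger) node index
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D.d[i, j])

    active = set(range(n))
    next_index = n
    while len(active) > 1:
        dmin = min(dist[key] for key in dist)
        candidates = [key for key, v in dist.items() if v == dmin]
        a, b = tie_break(candidates)
        na, nb = nodes[a], nodes[b]
        parent = TreeNode(
            index=next_index,
            height=dmin / 2.0,
            left=na,
            right=nb,
            members=na.members | nb.members,
        )
        nodes[next_index] = parent
        sa, sb = len(na.members), len(nb.members)
        active.discard(a)
        active.discard(b)
        for c in active:
            dac = dist.pop((min(a, c), max(a, c)))
            dbc = dist.pop((min(b, c), max(b, c)))
            dist[(min(next_index, c), max(next_index, c))] = (sa * dac + sb * dbc) / (sa + sb)
        dist.pop((a, b))
        active.add(next_index)
        next_index += 1

    root = nodes[next_index - 1]
    return GuideTree(root=root, n_leaves=n)


def post_order(tree: GuideTree) -> list[int]:
    """Node indices in post-order: left subtree, right subtree, node.

    Every parent appears after both of its children — the evaluation order
    of the progressive alignment.
    """
    out: list[int] = []
    stack: list[tuple[TreeNode, bool]] = [(tree.root, False)]
    while stack:
        node, expanded = stack.pop()
        if node.is_leaf or expanded:
            out.append(node.index)
        else:
            stack.append((node, True))
            if node.right is not None:
                stack.append((node.right, False))
            if node.left is not None:
                stack.append((node.left, False))
    return out


def node_depth(tree: GuideTree, node: "TreeNode | int") -> int:
    """Edges from the root (root = 0, children = parent + 1)."""
    target = node.index if isinstance(node, TreeNode) else int(node)
    stack = [(tree.root, 0)]
    while stack:
        current, depth = stack.pop()
        if current.index == target:
            return depth
        if current.left is not None:
            stack.append((current.left, depth + 1))
        if current.right is not None:
            stack.append((current.right, depth + 1))
    raise TreeError(f"node {target} not in tree")


def theoretical_balanced_speedup(n_nodes: int) -> float:
    """Best-case task-parallel traversal speedup (n - 1) / (2 h) for a
    fully balanced binary tree of n nodes, h = log2(n + 1) - 1.

    Only defined when n + 1 is a power of two (and h > 0): a balanced tree
    lets independent subtrees run concurrently, but the merges near the
    root serialize, capping the gain.
    """
    n = int(n_nodes)
    if n < 3 or (n + 1) & n != 0:
        raise TreeError("formula defined for fully balanced trees (n + 1 a power of two, n >= 3)")
    h = math.log2(n + 1) - 1
    return (n - 1) / (2 * h)


def to_newick(tree: GuideTree, labels: list[str]) -> str:
    """Newick serialization; branch length = parent height - child height."""
    if len(labels) != tree.n_leaves:
        raise TreeError(
            f"label count {len(labels)} does not match leaf count {tree.n_leaves}"
        )

    def fmt(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            body = labels[node.index]
        else:
            body = f"({fmt(node.left, node.height)},{fmt(node.right, node.height)})"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - node.height:.10g}"

    return fmt(tree.root, None) + ";"


def tree_table_tsv(tree: GuideTree) -> str:
    """Flat dump: one row per node (index, left, right, height)."""
    lines = ["index\tleft\tright\theight"]
    by_index = tree.nodes_by_index()
    for idx in sorted(by_index):
        node = by_index[idx]
        left = node.left.index if node.left is not None else ""
        right = node.right.index if node.right is not None else ""
        lines.append(f"{idx}\t{left}\t{right}\t{node.height!r}")
    return "\n".join(lines) + "\n"
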