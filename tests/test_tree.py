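import math

import dendropy
import numpy as np
import pytest

from tracealign.engine import DistanceMatrix
from tracealign.tree import (
    TreeError,
    node_depth,
    post_order,
    theoretical_balanced_speedup,
    tie_break,
    to_newick,
    tree_table_tsv,
    upgma,
)

from oracles import upgma_rescan


def _matrix(d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(n=d.shape[0], d=d)


def _random_matrix(rng, n):
    upper = rng.uniform(0.05, 1.0, size=(n, n))
    d = np.triu(upper, 1)
    return _matrix(d + d.T)


def _merge_sequence(tree):
    nodes = tree.nodes_by_index()
    return [
        (nodes[i].left.index, nodes[i].right.index, i, nodes[i].height)
        for i in sorted(nodes) if i >= tree.n_leaves
    ]


class TestUPGMA:
    def test_two_leaves(self):
        tree = upgma(_matrix([[0, 0.4], [0.4, 0]]))
        assert tree.root.index == 2
        assert tree.root.height == pytest.approx(0.2)
        assert {tree.root.left.index, tree.root.right.index} == {0, 1}

    def test_hand_executed_three_leaves(self):
        tree = upgma(_matrix([[0, 0.2, 0.6], [0.2, 0, 0.8], [0.6, 0.8, 0]]))
        nodes = tree.nodes_by_index()
        assert nodes[3].members == frozenset({0, 1})
        assert nodes[3].height == pytest.approx(0.1)
        assert nodes[4].height == pytest.approx(0.35)  # (0.6 + 0.8) / 2 / 2
        assert nodes[4].members == frozenset({0, 1, 2})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_full_rescan_oracle(self, seed):
        rng = np.random.default_rng(400 + seed)
        D = _random_matrix(rng, 5)
        tree = upgma(D)
        expected = upgma_rescan(D.d)
        got = _merge_sequence(tree)
        assert len(got) == len(expected)
        for (a1, b1, i1, h1), (a2, b2, i2, h2) in zip(got, expected):
            assert {a1, b1} == {a2, b2} and i1 == i2
            assert h1 == pytest.approx(h2, abs=1e-9)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_ultrametric_and_structural_invariants(self, n):
        rng = np.random.default_rng(n)
        tree = upgma(_random_matrix(rng, n))
        nodes = tree.nodes_by_index()
        assert len(nodes) == 2 * n - 1
        assert all(idx >= n for idx, node in nodes.items() if not node.is_leaf)
        # parent height >= child heights; members = union
        for node in nodes.values():
            if node.is_leaf:
                assert node.members == frozenset({node.index})
                continue
            assert node.height >= node.left.height - 1e-12
            assert node.height >= node.right.height - 1e-12
            assert node.members == node.left.members | node.right.members
        # equal root-to-leaf path lengths
        def leaf_depth_sum(node, acc):
            if node.is_leaf:
                yield acc + node.height  # leaf height is 0; acc counts branch lengths
            else:
                for child in (node.left, node.right):
                    yield from leaf_depth_sum(child, acc + (node.height - child.height))
        depths = list(leaf_depth_sum(tree.root, 0.0))
        assert max(depths) - min(depths) < 1e-9

    def test_cross_check_against_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(99)
        D = _random_matrix(rng, 6)
        tree = upgma(D)
        Z = average(squareform(D.d, checks=False))
        ours = sorted(node.height * 2 for node in tree.nodes_by_index().values()
                      if not node.is_leaf)
        theirs = sorted(Z[:, 2])
        np.testing.assert_allclose(ours, theirs, atol=1e-9)

    def test_too_small_rejected(self):
        with pytest.raises(TreeError):
            upgma(_matrix([[0.0]]))


class TestTieBreak:
    @pytest.mark.parametrize(
        "candidates,expected",
        [([(0, 2), (1, 3)], (0, 2)), ([(0, 3), (0, 2)], (0, 2)), ([(4, 1)], (1, 4))],
    )
    def test_lexicographic_rule(self, candidates, expected):
        assert tie_break(candidates) == expected


class TestTraversal:
    def test_two_leaf_post_order(self):
        tree = upgma(_matrix([[0, 0.4], [0.4, 0]]))
        assert post_order(tree) == [0, 1, 2]

    def test_balanced_four_leaves(self):
        # distances force merges (0,1) -> 4, (2,3) -> 5, then the root 6
        d = np.array([
            [0.0, 0.1, 0.9, 0.9],
            [0.1, 0.0, 0.9, 0.9],
            [0.9, 0.9, 0.0, 0.2],
            [0.9, 0.9, 0.2, 0.0],
        ])
        tree = upgma(_matrix(d))
        assert post_order(tree) == [0, 1, 4, 2, 3, 5, 6]

    def test_parent_after_children_property(self):
        rng = np.random.default_rng(17)
        tree = upgma(_random_matrix(rng, 7))
        order = post_order(tree)
        position = {idx: k for k, idx in enumerate(order)}
        for node in tree.nodes_by_index().values():
            if not node.is_leaf:
                assert position[node.index] > position[node.left.index]
                assert position[node.index] > position[node.right.index]

    def test_node_depths(self):
        tree = upgma(_matrix([[0, 0.4], [0.4, 0]]))
        assert node_depth(tree, tree.root) == 0
        assert node_depth(tree, 0) == 1
        assert node_depth(tree, 1) == 1
        with pytest.raises(TreeError):
            node_depth(tree, 99)

    def test_depth_is_parent_plus_one(self):
        rng = np.random.default_rng(23)
        tree = upgma(_random_matrix(rng, 6))
        for node in tree.nodes_by_index().values():
            if not node.is_leaf:
                d = node_depth(tree, node)
                assert node_depth(tree, node.left) == d + 1
                assert node_depth(tree, node.right) == d + 1


class TestBalancedSpeedup:
    @pytest.mark.parametrize("n,expected", [(3, 1.0), (7, 1.5), (15, 14 / 6)])
    def test_printed_formula_values(self, n, expected):
        assert theoretical_balanced_speedup(n) == pytest.approx(expected, rel=1e-12)
        h = math.log2(n + 1) - 1
        assert theoretical_balanced_speedup(n) == pytest.approx((n - 1) / (2 * h))

    @pytest.mark.parametrize("n", [4, 6, 8, 2])
    def test_unbalanced_rejected(self, n):
        with pytest.raises(TreeError, match="balanced"):
            theoretical_balanced_speedup(n)


class TestNewick:
    def test_two_leaf_string(self):
        tree = upgma(_matrix([[0, 0.4], [0.4, 0]]))
        assert to_newick(tree, ["A", "B"]) == "(A:0.2,B:0.2);"

    def test_round_trip_topology_with_dendropy(self):
        rng = np.random.default_rng(31)
        tree = upgma(_random_matrix(rng, 6))
        labels = [f"s{k}" for k in range(6)]
        text = to_newick(tree, labels)
        parsed = dendropy.Tree.get(data=text, schema="newick")
        assert sorted(leaf.taxon.label for leaf in parsed.leaf_node_iter()) == labels
        for edge in parsed.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0.0  # ultrametricity

    def test_label_mismatch_rejected(self):
        tree = upgma(_matrix([[0, 0.4], [0.4, 0]]))
        with pytest.raises(TreeError):
            to_newick(tree, ["only-one"])

    def test_table_dump_lists_every_node(self):
        rng = np.random.default_rng(37)
        tree = upgma(_random_matrix(rng, 5))
        lines = tree_table_tsv(tree).strip().split("\n")
        assert len(lines) == 1 + tree.n_nodes
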