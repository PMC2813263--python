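import itertools

import numpy as np
import pytest

from rolegraph.network import Assignment, Network
from rolegraph.objective import (
    BlockSums,
    FitScore,
    ImageGraph,
    balanced_penalty,
    block_sums,
    diagonal_score,
    read_off_image_graph,
    score_fixed,
    score_joint,
    subset_score,
)

from conftest import make_random_network, random_assignment


def brute_force_error(net, a, B, pm):
    """Independent pair-by-pair evaluation of the error function."""
    E = 0.0
    names = net.node_names
    for i in range(net.n):
        for j in range(i + 1, net.n):
            b = B.B[a.roles[i], a.roles[j]]
            if net.has_edge(names[i], names[j]):
                E += net.edge_weight(names[i], names[j]) * (1 - b)
            else:
                E += pm.p * b
    return E / pm.M


def enumerate_image_graphs(q):
    keys = [(r, s) for r in range(q) for s in range(r, q)]
    for bits in itertools.product((0, 1), repeat=len(keys)):
        B = np.zeros((q, q), dtype=np.int8)
        for (r, s), b in zip(keys, bits):
            B[r, s] = B[s, r] = b
        yield ImageGraph(B)


class TestBalancedPenalty:
    def test_path_on_four_nodes(self):
        net = Network.from_edges([("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)])
        pm = balanced_penalty(net)
        assert pm.W == 3 and pm.Z == 3 and pm.p == 1.0 and pm.M == 6.0

    def test_star_with_weight_two(self):
        net = Network.from_edges([("h", x, 2.0) for x in "abc"])
        pm = balanced_penalty(net)
        assert pm.W == 6 and pm.Z == 3 and pm.p == 2.0

    def test_complete_graph_rejected(self):
        net = Network.from_edges([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
        with pytest.raises(ValueError, match="complete"):
            balanced_penalty(net)


class TestBlockSums:
    def test_conservation_on_random_instances(self, rng):
        for _ in range(200):
            net = make_random_network(int(rng.integers(4, 12)), 0.4, rng)
            pm = balanced_penalty(net)
            q = int(rng.integers(1, 5))
            a = random_assignment(net, q, rng)
            m = block_sums(net, a, pm).m
            assert abs(m[np.triu_indices(q)].sum()) < 1e-9

    def test_matches_pairwise_brute_force(self, rng):
        net = make_random_network(6, 0.5, rng)
        pm = balanced_penalty(net)
        a = Assignment([0, 1, 0, 1, 1, 0], 2)
        m = block_sums(net, a, pm).m
        expect = np.zeros((2, 2))
        names = net.node_names
        for i in range(6):
            for j in range(i + 1, 6):
                r, s = sorted((a.roles[i], a.roles[j]))
                if net.has_edge(names[i], names[j]):
                    expect[r, s] += net.edge_weight(names[i], names[j])
                else:
                    expect[r, s] -= pm.p
        assert np.allclose(m, np.triu(expect) + np.triu(expect, 1).T, atol=1e-12)

    def test_role_permutation_permutes_matrix(self, rng):
        net = make_random_network(8, 0.4, rng)
        pm = balanced_penalty(net)
        a = random_assignment(net, 3, rng)
        perm = np.array([2, 0, 1])
        m1 = block_sums(net, a, pm).m
        m2 = block_sums(net, a.relabel(perm), pm).m
        assert np.allclose(m2[np.ix_(perm, perm)], m1)

    def test_single_role_conserves_exactly(self, rng):
        net = make_random_network(7, 0.4, rng)
        pm = balanced_penalty(net)
        a = Assignment(np.zeros(7, dtype=int), 1)
        assert abs(block_sums(net, a, pm).m[0, 0]) < 1e-12

    def test_unknown_node_coverage_rejected(self, rng):
        net = make_random_network(5, 0.5, rng)
        with pytest.raises(ValueError, match="covers"):
            block_sums(net, Assignment([0, 1], 2), balanced_penalty(net))


class TestScores:
    def test_edge_route_equals_block_route(self, rng):
        for _ in range(30):
            net = make_random_network(8, 0.4, rng)
            pm = balanced_penalty(net)
            q = int(rng.integers(2, 4))
            a = random_assignment(net, q, rng)
            for B in (ImageGraph.diagonal(q), read_off_image_graph(block_sums(net, a, pm))):
                sc = score_fixed(net, a, B, pm)
                assert abs(sc.E - brute_force_error(net, a, B, pm)) < 1e-12
                assert abs(sc.S - (1 - 2 * sc.E)) < 1e-12

    def test_all_zero_image_graph_single_role_half_error(self, rng):
        net = make_random_network(9, 0.4, rng)
        pm = balanced_penalty(net)
        a = Assignment(np.zeros(9, dtype=int), 1)
        sc = score_fixed(net, a, ImageGraph(np.zeros((1, 1), dtype=np.int8)), pm)
        assert abs(sc.E - 0.5) < 1e-12 and abs(sc.S) < 1e-12

    def test_joint_equals_enumeration_maximum(self, rng):
        for _ in range(20):
            net = make_random_network(6, 0.5, rng)
            pm = balanced_penalty(net)
            a = random_assignment(net, 2, rng)
            sj = score_joint(net, a, pm).S
            best = max(score_fixed(net, a, B, pm).S for B in enumerate_image_graphs(2))
            assert abs(sj - best) < 1e-12

    def test_single_role_joint_score_zero(self, rng):
        net = make_random_network(8, 0.4, rng)
        pm = balanced_penalty(net)
        assert abs(score_joint(net, Assignment(np.zeros(8, dtype=int), 1), pm).S) < 1e-12

    def test_toy_designed_fit_is_perfect(self, toy):
        from rolegraph.benchmark import TOY_IMAGE_GRAPH_PAIRS

        net, a = toy
        pm = balanced_penalty(net)
        B = ImageGraph.from_pairs(4, TOY_IMAGE_GRAPH_PAIRS)
        assert abs(score_fixed(net, a, B, pm).E) < 1e-12
        assert abs(score_joint(net, a, pm).S - 1.0) < 1e-12

    def test_label_permutation_invariance(self, rng):
        net = make_random_network(10, 0.3, rng)
        pm = balanced_penalty(net)
        a = random_assignment(net, 3, rng)
        perm = np.array([1, 2, 0])
        assert np.isclose(
            score_joint(net, a, pm).S, score_joint(net, a.relabel(perm), pm).S
        )
        B = ImageGraph.diagonal(3)
        assert np.isclose(
            score_fixed(net, a, B, pm).S, score_fixed(net, a.relabel(perm), B, pm).S
        )

    def test_dimension_mismatch_rejected(self, rng):
        net = make_random_network(6, 0.4, rng)
        pm = balanced_penalty(net)
        with pytest.raises(ValueError, match="q="):
            score_fixed(net, random_assignment(net, 3, rng), ImageGraph.diagonal(2), pm)

    def test_inconsistent_fit_score_rejected(self):
        with pytest.raises(ValueError, match="1 - 2E"):
            FitScore(S=0.5, E=0.5)


class TestReadOff:
    def test_sign_rule(self):
        m = BlockSums(np.array([[2.0, -1.0], [-1.0, 3.0]]))
        assert np.array_equal(read_off_image_graph(m).B, np.eye(2, dtype=np.int8))

    def test_zero_maps_to_absent_link(self):
        m = BlockSums(np.array([[0.0, 1.0], [1.0, -1.0]]))
        B = read_off_image_graph(m).B
        assert B[0, 0] == 0 and B[0, 1] == 1 and B[1, 1] == 0

    def test_read_off_achieves_joint_score(self, rng):
        for _ in range(200):
            net = make_random_network(int(rng.integers(5, 9)), 0.4, rng)
            pm = balanced_penalty(net)
            a = random_assignment(net, int(rng.integers(2, 4)), rng)
            bs = block_sums(net, a, pm)
            B = read_off_image_graph(bs)
            assert abs(score_fixed(net, a, B, pm).S - score_joint(net, a, pm).S) < 1e-9


class TestDiagonalScore:
    def test_two_cliques_exhaustive_maximum(self):
        net = Network()
        for c in range(2):
            for i in range(4):
                for j in range(i + 1, 4):
                    net.add_edge(f"c{c}{i}", f"c{c}{j}", 1.0)
        pm = balanced_penalty(net)
        clique_a = Assignment([0] * 4 + [1] * 4, 2)
        s_clique = diagonal_score(net, clique_a, pm).S
        best = max(
            diagonal_score(net, Assignment(list(bits), 2), pm).S
            for bits in itertools.product((0, 1), repeat=8)
        )
        assert abs(s_clique - best) < 1e-12

    def test_checkerboard_scores_negative(self):
        net = Network()
        for c in range(2):
            for i in range(4):
                for j in range(i + 1, 4):
                    net.add_edge(f"c{c}{i}", f"c{c}{j}", 1.0)
        pm = balanced_penalty(net)
        swapped = Assignment([0, 1, 0, 1, 1, 0, 1, 0], 2)
        assert diagonal_score(net, swapped, pm).S < 0

    def test_single_role_zero(self, rng):
        net = make_random_network(8, 0.4, rng)
        pm = balanced_penalty(net)
        assert abs(diagonal_score(net, Assignment(np.zeros(8, dtype=int), 1), pm).S) < 1e-12


class TestSubsetScore:
    def setup_method(self):
        self.net = Network.from_edges(
            [("a", "b", 1.0), ("c", "d", 3.0), ("a", "c", 2.0)]
        )
        self.a = Assignment([0, 0, 1, 1], 2)

    def test_all_matched(self):
        B = ImageGraph(np.ones((2, 2), dtype=np.int8))
        assert subset_score(self.net, [("a", "b"), ("c", "d")], self.a, B) == 1.0

    def test_none_matched(self):
        B = ImageGraph(np.zeros((2, 2), dtype=np.int8))
        assert subset_score(self.net, [("a", "b")], self.a, B) == 0.0

    def test_weighted_fraction(self):
        # permit only within-role blocks: a-b (w=1, forbidden? roles 0,0 ->
        # permitted) ... choose B so only c-d (weight 3) matches
        B = ImageGraph(np.array([[0, 0], [0, 1]], dtype=np.int8))
        assert subset_score(self.net, [("a", "b"), ("c", "d")], self.a, B) == 0.75

    def test_empty_subset_rejected(self):
        B = ImageGraph.diagonal(2)
        with pytest.raises(ValueError, match="empty"):
            subset_score(self.net, [], self.a, B)
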