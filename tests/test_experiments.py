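import collections

import numpy as np
import pytest
from scipy import stats

from rolegraph.annealer import AnnealConfig, anneal, q_scan
from rolegraph.benchmark import BenchmarkSpec, TOY_IMAGE_GRAPH_PAIRS, make_benchmark, make_toy_fig1
from rolegraph.experiments import (
    generalization_experiment,
    maslov_rewire,
    per_type_profile,
    randomized_baseline,
    split_links,
)
from rolegraph.network import EvidenceCategory, Network
from rolegraph.objective import balanced_penalty, score_joint

from conftest import make_random_network


def categorized_network(n, p_edge, rng, weights=(1, 2, 4)):
    net = Network()
    for i in range(n):
        net.add_node(f"n{i}")
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                cat = EvidenceCategory.from_weight(int(rng.choice(weights)))
                net.add_edge(f"n{i}", f"n{j}", float(cat.weight), cat)
    return net


def per_node_type_degrees(net):
    d = collections.Counter()
    for u, v, _, cat in net.edges():
        key = cat.label if cat else None
        d[(u, key)] += 1
        d[(v, key)] += 1
    return d


class TestMaslovRewire:
    def test_single_edge_per_category_unchanged(self):
        net = Network.from_edges(
            [
                ("a", "b", 1.0, EvidenceCategory.from_weight(1)),
                ("c", "d", 4.0, EvidenceCategory.from_weight(4)),
            ]
        )
        r = maslov_rewire(net, seed=0)
        assert sorted(r.edges()) == sorted(net.edges())

    def test_preserves_per_node_per_category_degrees(self, rng):
        for s in range(10):
            net = categorized_network(20, 0.25, rng)
            r = maslov_rewire(net, swaps_per_edge=10, seed=s)
            assert per_node_type_degrees(net) == per_node_type_degrees(r)
            assert net.categories() == r.categories()
            assert sorted(net.node_names) == sorted(r.node_names)

    def test_disjoint_pair_swaps_to_legal_rewiring(self):
        cat = EvidenceCategory.from_weight(1)
        net = Network.from_edges(
            [("a", "b", 1.0, cat), ("c", "d", 1.0, cat)]
        )
        outcomes = set()
        for s in range(20):
            r = maslov_rewire(net, swaps_per_edge=1, seed=s)
            outcomes.add(frozenset(frozenset((u, v)) for u, v, _, _ in r.edges()))
        legal = {
            frozenset({frozenset("ab"), frozenset("cd")}),
            frozenset({frozenset("ad"), frozenset("cb")}),
            frozenset({frozenset("ac"), frozenset("bd")}),
        }
        assert outcomes <= legal and len(outcomes) > 1

    def test_destroys_planted_structure(self):
        net, planted = make_benchmark(BenchmarkSpec(noise=0.0), seed=3)
        pm = balanced_penalty(net)
        r = maslov_rewire(net, swaps_per_edge=10, seed=1)
        pm_r = balanced_penalty(r)
        s_orig = score_joint(net, planted, pm).S
        # score the rewired copy under the planted labels: structure gone
        from rolegraph.network import Assignment

        planted_r = Assignment(
            [planted.roles[net.index(name)] for name in r.node_names], 4
        )
        assert score_joint(r, planted_r, pm_r).S < 0.5 * s_orig


class TestSplitLinks:
    def test_zero_test_size(self, rng):
        net = make_random_network(15, 0.3, rng)
        sp = split_links(net, 0, seed=1)
        assert sp.train.m == net.m and sp.test == []

    def test_sizes_and_weight_conservation(self, rng):
        net = make_random_network(20, 0.3, rng)
        sp = split_links(net, 10, seed=2)
        assert len(sp.test) == 10
        assert sp.train.m == net.m - 10
        assert sp.train.W + sp.test_weight == pytest.approx(net.W)
        assert sp.train.n == net.n  # endpoints of removed links remain

    def test_deterministic(self, rng):
        net = make_random_network(20, 0.3, rng)
        s1, s2 = split_links(net, 5, seed=7), split_links(net, 5, seed=7)
        assert s1.test == s2.test

    def test_oversized_test_rejected(self, rng):
        net = make_random_network(10, 0.3, rng)
        with pytest.raises(ValueError, match=">="):
            split_links(net, net.m, seed=0)


class TestGeneralization:
    def test_perfectly_fitting_structure_scores_one_on_heldout(self):
        net, _ = make_toy_fig1(idealized=True)
        from rolegraph.objective import ImageGraph

        B = ImageGraph.from_pairs(4, TOY_IMAGE_GRAPH_PAIRS)
        df = generalization_experiment(
            net, {4: B}, repetitions=3, test_size=8, seed=1,
            cfg=AnnealConfig(q=4, restarts=5),
        )
        assert df.test_score_fixed_mean.iloc[0] == pytest.approx(1.0)
        assert df.test_score_fixed_sd.iloc[0] == pytest.approx(0.0)

    def test_single_repetition_has_undefined_pvalue(self):
        net, _ = make_benchmark(
            BenchmarkSpec(n=64, class_sizes=(16,) * 4, mean_degree=8.0), seed=1
        )
        spec = BenchmarkSpec(n=64, class_sizes=(16,) * 4, mean_degree=8.0)
        df = generalization_experiment(
            net, {4: spec.image_graph()}, repetitions=1, test_size=20, seed=1,
            cfg=AnnealConfig(q=4, restarts=2),
        )
        assert np.isnan(df.p_value.iloc[0])

    def test_welch_pvalue_symmetric_in_samples(self, rng):
        x = rng.normal(0.8, 0.05, 10)
        y = rng.normal(0.6, 0.08, 10)
        p1 = stats.ttest_ind(x, y, equal_var=False).pvalue
        p2 = stats.ttest_ind(y, x, equal_var=False).pvalue
        assert p1 == pytest.approx(p2)


class TestRandomizedBaseline:
    def test_q1_scores_zero_and_determinism(self):
        net, _ = make_benchmark(
            BenchmarkSpec(n=64, class_sizes=(16,) * 4, mean_degree=8.0), seed=2
        )
        cfg = AnnealConfig(q=1, restarts=2)
        df1 = randomized_baseline(net, [1], realizations=2, cfg=cfg, seed=3)
        df2 = randomized_baseline(net, [1], realizations=2, cfg=cfg, seed=3)
        assert (df1.mean_score == 0.0).all()
        assert df1.equals(df2)


class TestPerTypeProfile:
    def test_single_category_network_has_unit_ratio(self, rng):
        net = categorized_network(16, 0.3, rng, weights=(4,))
        fits = q_scan(net, [2, 3], mode="joint",
                      cfg=AnnealConfig(q=3, restarts=3, seed=1))
        df = per_type_profile(net, fits)
        assert len(df) == 1
        assert df.mean_ratio.iloc[0] == pytest.approx(1.0)
        assert df.weight.iloc[0] == 4

    def test_random_category_scores_lowest(self, rng):
        # planted two-clique structure carried by in-vivo edges; Y2H edges
        # sprinkled uniformly at random ignore the block structure
        net = Network()
        vivo = EvidenceCategory.from_weight(4)
        y2h = EvidenceCategory.from_weight(1)
        for c in range(2):
            for i in range(8):
                for j in range(i + 1, 8):
                    if rng.random() < 0.8:
                        net.add_edge(f"c{c}_{i}", f"c{c}_{j}", 4.0, vivo)
        names = net.node_names
        added = 0
        while added < 12:
            u, v = rng.choice(names, size=2, replace=False)
            if not net.has_edge(u, v):
                net.add_edge(u, v, 1.0, y2h)
                added += 1
        fits = q_scan(net, [2, 3], mode="joint",
                      cfg=AnnealConfig(q=3, restarts=5, seed=2))
        df = per_type_profile(net, fits)
        ratios = dict(zip(df.category, df.mean_ratio))
        assert min(ratios, key=ratios.get) == y2h.label

    def test_requires_categories(self, rng):
        net = make_random_network(10, 0.3, rng)
        fits = q_scan(net, [2], mode="joint", cfg=AnnealConfig(q=2, restarts=2))
        with pytest.raises(ValueError, match="categories"):
            per_type_profile(net, fits)
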