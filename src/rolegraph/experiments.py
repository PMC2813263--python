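"""Evaluation procedures on a fitted network: degree/type-preserving
randomization, held-out-link generalization, and per-evidence-type fit
profiles.

The randomization control rewires the network while preserving every node's
number of interactions of every evidence type, then refits; a large score gap
between original and rewired copies shows the detected block structure is not
a by-product of the degree/type sequence.  The generalization experiment
removes a random test set of links, refits the node-to-role assignment on the
remaining links with the image graph held fixed, and scores the held-out links
— comparing non-diagonal against diagonal image graphs tells whether the extra
degrees of freedom generalize or overfit.  The per-type profile scores each
evidence category's edges separately under one fit, normalized by the
full-network value, exposing evidence types (e.g. yeast two-hybrid) whose
interactions follow a different block structure than the rest of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annealer import AnnealConfig, RoleFit, anneal
from .network import Assignment, EvidenceCategory, Network
from .objective import ImageGraph, balanced_penalty, score_joint, subset_score

__all__ = [
    "LinkSplit",
    "maslov_rewire",
    "randomized_baseline",
    "split_links",
    "generalization_experiment",
    "per_type_profile",
]


def maslov_rewire(net: Network, swaps_per_edge: int = 10, seed: int = 0) -> Network:
    """Degree-preserving randomization by repeated two-edge swaps.

    Edges are only swapped within the same evidence category, so every node
    keeps its number of interactions of every type; a swap is rejected if it
    would create a self-loop or an edge that already exists (in any category).
    Targets ``swaps_per_edge`` accepted swaps per edge per category; categories
    with fewer than two edges pass through unchanged.
    """
    rng = np.random.default_rng(seed)
    # bucket edges by category label (None = uncategorised bucket)
    buckets: dict = {}
    for u, v, w, cat in net.edges():
        key = cat.label if cat is not None else None
        buckets.setdefault(key, []).append([u, v, w, cat])
    existing = {frozenset((u, v)) for u, v, _, _ in net.edges()}

    for key, edges in buckets.items():
        n_edges = len(edges)
        if n_edges < 2:
            continue
        target = swaps_per_edge * n_edges
        accepted = 0
        attempts = 0
        max_attempts = 200 * target
        while accepted < target and attempts < max_attempts:
            attempts += 1
            e1, e2 = rng.integers(0, n_edges, size=2)
            if e1 == e2:
                continue
            a, b, w1, c1 = edges[e1]
            c, d, w2, c2 = edges[e2]
            if len({a, b, c, d}) < 4:
                continue  # shared node: swap would self-loop or duplicate
            # two legal rewirings: (a-d, c-b) or (a-c, b-d)
            if rng.random() < 0.5:
                new1, new2 = (a, d), (c, b)
            else:
                new1, new2 = (a, c), (b, d)
            k1, k2 = frozenset(new1), frozenset(new2)
            if k1 in existing or k2 in existing or k1 == k2:
                continue
            existing.discard(frozenset((a, b)))
            existing.discard(frozenset((c, d)))
            existing.add(k1)
            existing.add(k2)
            edges[e1] = [new1[0], new1[1], w1, c1]
            edges[e2] = [new2[0], new2[1], w2, c2]
            accepted += 1

    out = Network()
    for name in net.node_names:
        out.add_node(name)
    for edges in buckets.values():
        for u, v, w, cat in edges:
            out.add_edge(u, v, w, cat)
    return out


def randomized_baseline(
    net: Network,
    q_list: Sequence[int],
    realizations: int = 10,
    cfg: Optional[AnnealConfig] = None,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Best joint and diagonal scores on rewired copies of the network.

    Returns one row per (q, mode) with the mean and standard deviation over
    ``realizations`` independently rewired copies.  Deterministic given seed.
    """
    base = cfg if cfg is not None else AnnealConfig(q=max(q_list))
    ss = np.random.SeedSequence(seed)
    rows = []
    rewired = []
    for child in ss.spawn(realizations):
        st = child.generate_state(2)
        rewired.append(
            (maslov_rewire(net, swaps_per_edge, seed=int(st[0] % 2**31)),
             int(st[1] % 2**31))
        )
    for q in q_list:
        for mode in ("joint", "diagonal"):
            scores = [
                anneal(rnet, replace(base, q=q, mode=mode, B=None, seed=s)).score.S
                for rnet, s in rewired
            ]
            rows.append(
                {
                    "q": q,
                    "mode": mode,
                    "mean_score": float(np.mean(scores)),
                    "sd_score": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
                    "realizations": realizations,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class LinkSplit:
    """A train/test partition of a network's links."""

    train: Network
    test: list  # (u, v, weight, category) tuples
    test_size: int
    seed: int

    @property
    def test_weight(self) -> float:
        return float(sum(e[2] for e in self.test))


def split_links(net: Network, test_size: int, seed: int = 0) -> LinkSplit:
    """Uniform random split of the links into a training network and test set.

    Test edges are removed from the training copy (their endpoints stay, so
    assignments remain defined on the full node set); removed pairs become
    absent pairs of the training network.
    """
    edges = list(net.edges())
    if test_size >= len(edges):
        raise ValueError(f"test_size {test_size} >= edge count {len(edges)}")
    rng = np.random.default_rng(seed)
    test_idx = set(rng.choice(len(edges), size=test_size, replace=False).tolist())
    train = Network()
    for name in net.node_names:
        train.add_node(name)
    test = []
    for k, (u, v, w, cat) in enumerate(edges):
        if k in test_idx:
            test.append((u, v, w, cat))
        else:
            train.add_edge(u, v, w, cat)
    if test_size > 0 and train.W == 0:
        import warnings

        warnings.warn("training network has zero edge weight; scores undefined")
    return LinkSplit(train=train, test=test, test_size=test_size, seed=seed)


def generalization_experiment(
    net: Network,
    image_graphs: dict[int, ImageGraph],
    repetitions: int = 10,
    test_size: int = 100,
    cfg: Optional[AnnealConfig] = None,
    seed: int = 0,
    welch: bool = True,
) -> pd.DataFrame:
    """Held-out-link scores of fixed non-diagonal vs diagonal image graphs.

    For each repetition a fresh train/test split is drawn; for each q the
    node-to-role assignment is re-optimized on the training links only, once
    with the given (fixed) image graph and once with the diagonal image graph
    of the same q; the held-out links are then scored as the matched-weight
    fraction under the trained assignment.  Returns per-q means, standard
    deviations and a two-sided t-test p-value (Welch by default) for a
    difference between the two models' test scores; the p-value is NaN when
    ``repetitions`` is 1.
    """
    base = cfg if cfg is not None else AnnealConfig(q=max(image_graphs))
    ss = np.random.SeedSequence(seed)
    scores: dict[int, dict[str, list[float]]] = {
        q: {"fixed": [], "diagonal": []} for q in image_graphs
    }
    for child in ss.spawn(repetitions):
        st = child.generate_state(2)
        split = split_links(net, test_size, seed=int(st[0] % 2**31))
        run_seed = int(st[1] % 2**31)
        for q, B in image_graphs.items():
            for label, Bq in (("fixed", B), ("diagonal", ImageGraph.diagonal(q))):
                fit = anneal(
                    split.train,
                    replace(base, q=q, mode="fixed", B=Bq, seed=run_seed),
                )
                s = subset_score(split.train, split.test, fit.assignment, Bq)
                scores[q][label].append(s)
    rows = []
    for q in sorted(image_graphs):
        fx, dg = scores[q]["fixed"], scores[q]["diagonal"]
        if repetitions > 1:
            p_val = float(
                stats.ttest_ind(fx, dg, equal_var=not welch).pvalue
            )
        else:
            p_val = float("nan")
        rows.append(
            {
                "q": q,
                "test_score_fixed_mean": float(np.mean(fx)),
                "test_score_fixed_sd": float(np.std(fx, ddof=1)) if repetitions > 1 else 0.0,
                "test_score_diagonal_mean": float(np.mean(dg)),
                "test_score_diagonal_sd": float(np.std(dg, ddof=1)) if repetitions > 1 else 0.0,
                "p_value": p_val,
                "repetitions": repetitions,
            }
        )
    return pd.DataFrame(rows)


def per_type_profile(net: Network, fits: Sequence[RoleFit]) -> pd.DataFrame:
    """Per-evidence-weight fit ratios, averaged over the given fits.

    For each evidence category present in the network, the category's edges
    are scored (matched-weight fraction) under each fit's assignment and image
    graph, divided by the same score on all edges, and the ratios averaged
    over the fits (typically a scan over q).  Categories absent from the
    network are omitted with a warning.
    """
    by_cat: dict[str, list] = {}
    for u, v, w, cat in net.edges():
        if cat is None:
            continue
        by_cat.setdefault(cat.label, []).append((u, v, w))
    if not by_cat:
        raise ValueError("network carries no evidence categories")
    all_edges = [(u, v, w) for u, v, w, _ in net.edges()]

    rows = []
    for label, cat_edges in sorted(
        by_cat.items(), key=lambda kv: EvidenceCategory.from_tokens(
            parseable_label_tokens(kv[0])
        ).weight,
    ):
        weight = EvidenceCategory.from_tokens(parseable_label_tokens(label)).weight
        ratios = []
        for fit in fits:
            full = subset_score(net, all_edges, fit.assignment, fit.image_graph)
            part = subset_score(net, cat_edges, fit.assignment, fit.image_graph)
            ratios.append(part / full if full > 0 else float("nan"))
        rows.append(
            {
                "weight": weight,
                "category": label,
                "mean_ratio": float(np.nanmean(ratios)),
                "sd_ratio": float(np.nanstd(ratios, ddof=1)) if len(ratios) > 1 else 0.0,
                "n_fits": len(fits),
                "n_edges": len(cat_edges),
            }
        )
    return pd.DataFrame(rows)


def parseable_label_tokens(label: str) -> list[str]:
    """Split a canonical category label back into its evidence tokens."""
    return label.split("+")
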