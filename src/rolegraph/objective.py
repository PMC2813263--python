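"""Balanced-penalty error and fit-score functions for image-graph fitting.

Given a network with weighted adjacency ``w_ij``, an assignment sigma of nodes
into ``q`` roles and a binary ``q x q`` image graph ``B``, the error of the fit
counts the weight of edges falling into forbidden role pairs plus a penalty
``p`` for every absent node pair falling into a permitted role pair::

    E = (1/M) * [ sum_{edges (i,j)} w_ij * (1 - B[si, sj])
                  + p * sum_{absent pairs (i,j)} B[si, sj] ]

``p`` is chosen so the total error weight available on edges equals that on
absent pairs (``p = W/Z``, the *balanced penalty*), and ``M = W + p*Z = 2W``
bounds the error by 1.  The canonical score is ``S = 1 - 2E`` in [-1, 1]:
perfect fit scores 1, a structureless single-role fit scores 0.

All pair sums run over unordered pairs ``i < j``; within-role pairs count
once.  The per-block aggregates

    m_rs = (edge weight inside block {r,s}) - p * (absent pairs in block {r,s})

carry all the information: ``S = (1/M) * sum_{r<=s} (2*B_rs - 1) * m_rs``
under the balanced penalty (where ``sum m_rs = 0`` holds exactly), and the
best image graph for a fixed assignment is read off as ``B_rs = 1`` iff
``m_rs > 0``, giving the joint score ``S* = (1/M) * sum_{r<=s} |m_rs|``.
Fitting the diagonal image graph (only self-links) is equivalent to
modularity-style cohesive clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .network import Assignment, Network

__all__ = [
    "PenaltyModel",
    "BlockSums",
    "ImageGraph",
    "FitScore",
    "balanced_penalty",
    "block_sums",
    "score_fixed",
    "score_joint",
    "read_off_image_graph",
    "diagonal_score",
    "subset_score",
]


@dataclass(frozen=True)
class PenaltyModel:
    """Penalty per absent pair and the derived normalization constants."""

    p: float  # penalty charged to an absent pair inside a permitted block
    W: float  # total edge weight
    Z: int    # number of absent unordered pairs
    M: float  # normalization W + p*Z (== 2W when balanced)

    def __post_init__(self):
        if self.p < 0:
            raise ValueError("penalty p must be >= 0")
        if self.M <= 0:
            raise ValueError("normalization M must be > 0")


def balanced_penalty(net: Network) -> PenaltyModel:
    """Penalty model with ``p = W/Z`` so edge and absent-pair error balance."""
    n = net.n
    W = net.W
    if W <= 0:
        raise ValueError("network must have positive total edge weight")
    Z = n * (n - 1) // 2 - net.m
    if Z == 0:
        raise ValueError("penalty undefined for complete graph (no absent pairs)")
    p = W / Z
    return PenaltyModel(p=p, W=W, Z=Z, M=W + p * Z)


@dataclass
class BlockSums:
    """Symmetric q x q matrix of per-block aggregates m_rs."""

    m: np.ndarray

    @property
    def q(self) -> int:
        return self.m.shape[0]

    def upper_sum(self, f=None) -> float:
        """Sum of f(m_rs) over unordered role pairs r <= s."""
        iu = np.triu_indices(self.q)
        vals = self.m[iu]
        return float(np.sum(vals if f is None else f(vals)))


@dataclass(frozen=True)
class ImageGraph:
    """Symmetric binary role-interaction graph (self-links allowed)."""

    B: np.ndarray

    def __post_init__(self):
        B = np.asarray(self.B, dtype=np.int8)
        if B.ndim != 2 or B.shape[0] != B.shape[1]:
            raise ValueError("image graph must be a square matrix")
        if not np.array_equal(B, B.T):
            raise ValueError("image graph must be symmetric")
        if not np.isin(B, (0, 1)).all():
            raise ValueError("image graph entries must be 0 or 1")
        object.__setattr__(self, "B", B)

    @property
    def q(self) -> int:
        return self.B.shape[0]

    @property
    def is_diagonal(self) -> bool:
        return bool(np.array_equal(self.B, np.diag(np.diag(self.B))))

    @staticmethod
    def diagonal(q: int) -> "ImageGraph":
        """The diagonal image graph: q isolated self-linked roles."""
        return ImageGraph(np.eye(q, dtype=np.int8))

    @staticmethod
    def from_pairs(q: int, pairs: Iterable[tuple[int, int]]) -> "ImageGraph":
        B = np.zeros((q, q), dtype=np.int8)
        for r, s in pairs:
            B[r, s] = B[s, r] = 1
        return ImageGraph(B)

    def role_pairs(self) -> list[tuple[int, int]]:
        r, s = np.nonzero(np.triu(self.B))
        return list(zip(r.tolist(), s.tolist()))

    def to_json_dict(self) -> dict:
        return {"q": self.q, "matrix": self.B.astype(int).tolist()}

    @staticmethod
    def from_json_dict(d: dict) -> "ImageGraph":
        return ImageGraph(np.asarray(d["matrix"], dtype=np.int8))


@dataclass(frozen=True)
class FitScore:
    """Canonical score S in [-1, 1] with its error E = (1 - S)/2."""

    S: float
    E: float
    context: str = ""

    def __post_init__(self):
        if abs(self.S - (1.0 - 2.0 * self.E)) > 1e-9:
            raise ValueError("inconsistent score/error pair: S must equal 1 - 2E")


def _check_assignment(net: Network, a: Assignment) -> None:
    if len(a) != net.n:
        raise ValueError(
            f"assignment covers {len(a)} nodes but network has {net.n}"
        )


def block_sums(net: Network, a: Assignment, pm: PenaltyModel) -> BlockSums:
    """Per role-pair aggregates m_rs (edge weight minus penalised absences).

    Empty roles yield zero rows and columns.  Under the balanced penalty the
    aggregates conserve exactly: sum over r <= s of m_rs == 0.
    """
    _check_assignment(net, a)
    q = a.q
    sigma = a.roles
    wblk = np.zeros((q, q))
    eblk = np.zeros((q, q), dtype=np.int64)
    for i, j, w in net.iter_edge_indices():
        r, s = sigma[i], sigma[j]
        if r > s:
            r, s = s, r
        wblk[r, s] += w
        eblk[r, s] += 1
    counts = a.counts()
    pairs = np.outer(counts, counts).astype(np.float64)
    np.fill_diagonal(pairs, counts * (counts - 1) / 2.0)
    pairs = np.triu(pairs)
    m_upper = wblk - pm.p * (pairs - eblk)
    m = np.triu(m_upper) + np.triu(m_upper, 1).T
    return BlockSums(m=m)


def score_fixed(
    net: Network, a: Assignment, B: ImageGraph, pm: PenaltyModel
) -> FitScore:
    """Error/score of a fixed image graph under a fixed assignment."""
    if B.q != a.q:
        raise ValueError(f"image graph is {B.q}x{B.q} but assignment has q={a.q}")
    bs = block_sums(net, a, pm)
    iu = np.triu_indices(a.q)
    # E = (1/M) (W - sum_{r<=s} B_rs m_rs); S = 1 - 2E
    E = (pm.W - float(np.sum(B.B[iu] * bs.m[iu]))) / pm.M
    return FitScore(S=1.0 - 2.0 * E, E=E, context="fixed")


def score_joint(net: Network, a: Assignment, pm: PenaltyModel) -> FitScore:
    """Score of the assignment under its own best image graph.

    Equals the maximum of :func:`score_fixed` over all 2^(q(q+1)/2) image
    graphs, achieved by permitting exactly the blocks with m_rs > 0.
    """
    bs = block_sums(net, a, pm)
    S = bs.upper_sum(np.abs) / pm.M
    return FitScore(S=S, E=(1.0 - S) / 2.0, context="joint")


def read_off_image_graph(m: BlockSums) -> ImageGraph:
    """Best image graph for given block sums: B_rs = 1 iff m_rs > 0."""
    return ImageGraph((m.m > 0).astype(np.int8))


def diagonal_score(net: Network, a: Assignment, pm: PenaltyModel) -> FitScore:
    """Score under the diagonal image graph (cohesive-module objective).

    With the balanced uniform penalty this is the modularity-style quality
    used for ordinary graph clustering.
    """
    sc = score_fixed(net, a, ImageGraph.diagonal(a.q), pm)
    return FitScore(S=sc.S, E=sc.E, context="diagonal")


def subset_score(
    net: Network,
    edge_subset: Iterable[tuple[str, str]],
    a: Assignment,
    B: ImageGraph,
) -> float:
    """Matched-weight fraction of an edge subset under (assignment, B).

    Returns the weight of subset edges falling inside permitted blocks divided
    by the total subset weight — a value in [0, 1].  Only edge terms enter: a
    subset of edges has no well-defined complement of absent pairs, and the
    normalization is by the subset's own weight so scores of subsets of very
    different size are directly comparable.
    """
    _check_assignment(net, a)
    sigma = a.roles
    total = 0.0
    matched = 0.0
    for item in edge_subset:
        u, v = item[0], item[1]
        # items may carry their own weight (e.g. held-out edges absent from net)
        w = float(item[2]) if len(item) > 2 and item[2] is not None else net.edge_weight(u, v)
        total += w
        if B.B[sigma[net.index(u)], sigma[net.index(v)]]:
            matched += w
    if total <= 0:
        raise ValueError("edge subset is empty or has zero weight")
    return matched / total
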