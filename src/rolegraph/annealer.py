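"""Simulated-annealing optimization of role assignments.

Two objectives are supported: the *joint* objective, which scores an
assignment under its own best image graph (read off from the block-sum signs),
and the *fixed* objective for a given image graph ``B`` (the diagonal image
graph recovers modularity-style cohesive clustering).  Local moves reassign a
single node; one such move costs O(degree + q) via incremental block sums.

Moves are accepted by the Metropolis rule (always if the score does not
decrease, else with probability exp(dS/T)) under a geometric cooling schedule.
Multiple restarts from random initial assignments are run and the best-scoring
result is returned; given a seed the whole procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .network import Assignment, Network
from .objective import (
    FitScore,
    ImageGraph,
    PenaltyModel,
    balanced_penalty,
    block_sums,
    read_off_image_graph,
    score_fixed,
    score_joint,
)

__all__ = ["AnnealConfig", "AnnealState", "RoleFit", "move_delta", "anneal", "q_scan"]


@dataclass(frozen=True)
class AnnealConfig:
    """Annealing schedule and restart policy.

    ``cooling=None`` resolves to 0.99 for q < 10 and 0.999 otherwise;
    ``T0=None`` auto-calibrates to the mean absolute move delta of an initial
    sweep (a typical downhill move starts ~1/e-acceptable), which starts the
    schedule just above the ordering transition rather than deep in the
    disordered phase.  A sweep proposes one move per node in random order; a run
    stops when the best score has not improved for ``patience`` consecutive
    temperature steps or T drops below ``T_min``.
    """

    q: int
    mode: str = "joint"  # joint | diagonal | fixed
    B: Optional[ImageGraph] = None  # required for mode == "fixed"
    T0: Optional[float] = None
    cooling: Optional[float] = None
    sweeps_per_T: int = 3
    T_min: float = 1e-6
    patience: int = 20
    restarts: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.mode not in ("joint", "diagonal", "fixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "fixed" and self.B is None:
            raise ValueError("mode 'fixed' requires an image graph B")
        if self.B is not None and self.B.q != self.q:
            raise ValueError("image graph size must match q")
        if self.cooling is not None and not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling factor must lie in (0, 1)")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")

    def resolved_cooling(self) -> float:
        if self.cooling is not None:
            return self.cooling
        return 0.99 if self.q < 10 else 0.999

    def image_graph(self) -> Optional[ImageGraph]:
        if self.mode == "diagonal":
            return ImageGraph.diagonal(self.q)
        return self.B


@dataclass
class RoleFit:
    """Result of an annealing run: assignment, image graph and score."""

    assignment: Assignment
    image_graph: ImageGraph
    score: FitScore
    restart_scores: list = field(default_factory=list)
    seed: int = 0
    config: Optional[AnnealConfig] = None


class AnnealState:
    """Incremental objective state for single-node role moves.

    Maintains per-block edge weights and counts so that the score change of
    moving one node can be evaluated in O(degree + q) without rescoring the
    whole network.
    """

    def __init__(
        self,
        net: Network,
        a: Assignment,
        pm: PenaltyModel,
        mode: str = "joint",
        B: Optional[ImageGraph] = None,
    ) -> None:
        if len(a) != net.n:
            raise ValueError("assignment does not cover the network")
        self.net = net
        self.q = a.q
        self.pm = pm
        self.mode_int = 0 if mode == "joint" else 1
        if mode == "joint":
            self.coef = np.zeros((self.q, self.q))
        else:
            Bmat = ImageGraph.diagonal(self.q) if B is None else B
            if Bmat.q != self.q:
                raise ValueError("image graph size must match q")
            self.coef = 2.0 * Bmat.B.astype(np.float64) - 1.0
        self.indptr, self.nbr, self.wts = net.csr()
        self.sigma = a.roles.astype(np.int64).copy()
        self.counts, self.wblk, self.eblk = _kernels.block_state_init(
            self.indptr, self.nbr, self.wts, self.sigma, self.q
        )
        self._wrole = np.zeros(self.q)
        self._crole = np.zeros(self.q, dtype=np.int64)

    def assignment(self) -> Assignment:
        return Assignment(self.sigma.copy(), self.q)

    def score(self) -> float:
        return (
            _kernels.block_objective(
                self.counts, self.wblk, self.eblk, self.pm.p, self.q,
                self.mode_int, self.coef,
            )
            / self.pm.M
        )

    def _check(self, node: int, new_role: int) -> None:
        if not (0 <= node < self.sigma.size):
            raise ValueError(f"unknown node index {node}")
        if not (0 <= new_role < self.q):
            raise ValueError(f"unknown role {new_role} (q={self.q})")

    def move_delta(self, node: int, new_role: int) -> float:
        """Score change of moving ``node`` to ``new_role`` (state unchanged)."""
        self._check(node, new_role)
        return (
            _kernels.move_delta_raw(
                self.indptr, self.nbr, self.wts, self.sigma, self.counts,
                self.wblk, self.eblk, self.pm.p, self.q, self.mode_int,
                self.coef, node, new_role, self._wrole, self._crole,
            )
            / self.pm.M
        )

    def apply(self, node: int, new_role: int) -> None:
        self._check(node, new_role)
        _kernels.apply_move_raw(
            self.indptr, self.nbr, self.wts, self.sigma, self.counts,
            self.wblk, self.eblk, self.q, node, new_role,
            self._wrole, self._crole,
        )


def move_delta(state: AnnealState, node: int, new_role: int) -> float:
    """Incremental score change of a single-node move (see AnnealState)."""
    return state.move_delta(node, new_role)


def _final_fit(net, pm, a, cfg) -> tuple[ImageGraph, FitScore]:
    if cfg.mode == "joint":
        bs = block_sums(net, a, pm)
        return read_off_image_graph(bs), score_joint(net, a, pm)
    B = cfg.image_graph()
    sc = score_fixed(net, a, B, pm)
    return B, sc


def anneal(
    net: Network,
    cfg: AnnealConfig,
    init_assignment: Optional[Assignment] = None,
) -> RoleFit:
    """Best-of-restarts annealed fit of the configured objective.

    Each restart starts from an independent uniform-random assignment drawn
    from a counter-based substream of ``cfg.seed`` (restart k always sees the
    same stream regardless of the total restart count).  If
    ``init_assignment`` is given it seeds the first restart (warm start).
    The returned score is re-evaluated from scratch on the winning assignment.
    """
    pm = balanced_penalty(net)
    q = cfg.q
    if q == 1:
        a = Assignment(np.zeros(net.n, dtype=np.int64), 1)
        B, sc = _final_fit(net, pm, a, cfg)
        return RoleFit(a, B, sc, [sc.S], cfg.seed, cfg)

    indptr, nbr, wts = net.csr()
    coef = (
        np.zeros((q, q))
        if cfg.mode == "joint"
        else 2.0 * cfg.image_graph().B.astype(np.float64) - 1.0
    )
    mode_int = 0 if cfg.mode == "joint" else 1
    cooling = cfg.resolved_cooling()
    T0 = -1.0 if cfg.T0 is None else float(cfg.T0)

    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.restarts)
    best_sigma = None
    best_score = -np.inf
    traces = []
    for k in range(cfg.restarts):
        state = children[k].generate_state(2)
        rng = np.random.default_rng(children[k])
        if k == 0 and init_assignment is not None:
            if len(init_assignment) != net.n or init_assignment.q > q:
                raise ValueError("init_assignment incompatible with network/q")
            sigma0 = init_assignment.roles.astype(np.int64).copy()
        else:
            sigma0 = rng.integers(0, q, size=net.n).astype(np.int64)
        kernel_seed = int(state[0] % np.int64(2**31 - 1))
        sig, score, _ = _kernels.anneal_run(
            indptr, nbr, wts, pm.p, pm.M, q, mode_int, coef, sigma0,
            T0, cooling, cfg.sweeps_per_T, cfg.T_min, cfg.patience,
            kernel_seed,
        )
        traces.append(float(score))
        if score > best_score + 1e-12:  # ties keep the first encountered
            best_score = float(score)
            best_sigma = sig

    a = Assignment(best_sigma, q)
    B, sc = _final_fit(net, pm, a, cfg)
    if abs(sc.S - best_score) > 1e-6:
        raise AssertionError(
            f"incremental score {best_score} disagrees with re-evaluation {sc.S}"
        )
    return RoleFit(a, B, sc, traces, cfg.seed, cfg)


def q_scan(
    net: Network,
    q_list: Sequence[int],
    mode: str = "joint",
    cfg: Optional[AnnealConfig] = None,
) -> list[RoleFit]:
    """Anneal over an ascending list of maximum role counts.

    Each q is warm-started with the previous optimum embedded as one initial
    condition; since unused roles are free, the best joint score is then
    non-decreasing in q by construction.
    """
    if list(q_list) != sorted(q_list):
        raise ValueError("q_list must be sorted ascending")
    if mode == "fixed":
        raise ValueError("q_scan supports modes 'joint' and 'diagonal'")
    base = cfg if cfg is not None else AnnealConfig(q=max(q_list), mode=mode)
    fits: list[RoleFit] = []
    prev: Optional[Assignment] = None
    for q in q_list:
        cfg_q = replace(base, q=q, mode=mode, B=None, seed=base.seed + q)
        fit = anneal(net, cfg_q, init_assignment=prev)
        fits.append(fit)
        prev = Assignment(fit.assignment.roles.copy(), q)
    return fits
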