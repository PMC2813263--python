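"""Comparison methods: symmetric NMF tri-factorization and the
Newman-Leicht mixture model.

Both methods assign the nodes of a network to ``q`` latent classes and serve
as baselines for the planted-structure benchmark.  By default they operate on
the binarized adjacency matrix; pass ``binary=False`` to feed edge weights.

*NMF* factorizes the adjacency as ``A ~ H S H^T`` with ``H`` (n x q) and ``S``
(q x q) nonnegative, minimizing the generalized Kullback-Leibler divergence
``D(A || HSH^T) = sum A log(A/Ahat) - A + Ahat``.  Multiplicative updates
follow the usual positive/negative gradient split; because ``H`` enters the
model twice, its update uses a square-root damping which keeps the objective
monotone in practice.  Nodes are assigned to the class with the largest entry
in their row of ``H`` (ties to the lowest index), so non-diagonal block
structure is representable through the off-diagonal entries of ``S``.

*Newman-Leicht* is a mixture model in which each latent class ``r`` has a
prior ``pi_r`` and a distribution ``theta_r`` over which nodes its members
link to; the likelihood of node i under class r is prod_j theta_rj^{A_ij}.
Fitting is by EM (responsibilities in the E-step, closed-form ``pi``/``theta``
in the M-step); the log-likelihood is non-decreasing by the usual EM
guarantee.  The directed formulation of the original model is applied
symmetrically, counting each undirected edge at both endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .network import Assignment, Network

__all__ = [
    "NMFFactors",
    "MixtureParams",
    "nmf_fit",
    "nmf_assign",
    "nl_em_fit",
    "nl_assign",
    "best_nmf_assignment",
    "best_nl_assignment",
]

_EPS = 1e-12


def _adjacency(net: Network, binary: bool) -> np.ndarray:
    A = net.adjacency()
    if binary:
        A = (A > 0).astype(np.float64)
    return A


@dataclass
class NMFFactors:
    """Fitted factors H (n x q), S (q x q) and the per-iteration KL trace."""

    H: np.ndarray
    S_mat: np.ndarray
    kl_trace: np.ndarray


def _gen_kl(A: np.ndarray, Ahat: np.ndarray, mask: np.ndarray) -> float:
    pos = (A > 0) & (mask > 0)
    return float(
        np.sum(A[pos] * np.log(A[pos] / np.maximum(Ahat[pos], _EPS)))
        - (A * mask).sum()
        + (Ahat * mask).sum()
    )


def nmf_fit(
    net: Network,
    q: int,
    iters: int = 100,
    seed: int = 0,
    binary: bool = True,
) -> NMFFactors:
    """Symmetric tri-factorization by damped multiplicative KL updates.

    Runs exactly ``iters`` iterations (each updating S exactly and H with a
    1/2-power damped multiplicative step).  ``kl_trace`` holds the divergence
    before any update followed by the value after each iteration.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    if q > net.n:
        raise ValueError(f"q={q} exceeds node count {net.n}")
    A = _adjacency(net, binary)
    n = net.n
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(A.mean(), _EPS) / max(q, 1))
    H = rng.uniform(0.5, 1.5, size=(n, q)) * scale
    S = rng.uniform(0.5, 1.5, size=(q, q))
    S = (S + S.T) / 2.0

    # self-pairs carry no information in a simple graph; the divergence is
    # taken over off-diagonal entries only
    mask = np.ones((n, n)) - np.eye(n)
    trace = [_gen_kl(A, H @ S @ H.T, mask)]
    for _ in range(iters):
        # S update: exact multiplicative minimizer step (model linear in S)
        Ahat = np.maximum(H @ S @ H.T, _EPS)
        R = mask * (A / Ahat)
        num = H.T @ R @ H
        den = np.maximum(H.T @ mask @ H, _EPS)
        S = S * (num / den)
        S = (S + S.T) / 2.0
        # H update: damped (sqrt) multiplicative step for the twice-occurring factor
        Ahat = np.maximum(H @ S @ H.T, _EPS)
        R = mask * (A / Ahat)
        HS = H @ S
        num = R @ HS
        den = np.maximum(mask @ HS, _EPS)
        H = H * np.sqrt(num / den)
        trace.append(_gen_kl(A, H @ S @ H.T, mask))
    return NMFFactors(H=H, S_mat=S, kl_trace=np.asarray(trace))


def nmf_assign(f: NMFFactors) -> Assignment:
    """Assign each node to the class with the largest row entry of H.

    ``np.argmax`` breaks ties towards the lowest class index.
    """
    roles = np.argmax(f.H, axis=1)
    return Assignment(roles, f.H.shape[1])


@dataclass
class MixtureParams:
    """Newman-Leicht mixture parameters and per-node responsibilities."""

    pi: np.ndarray        # class priors, simplex over q
    theta: np.ndarray     # q x n, each row a distribution over link targets
    resp: np.ndarray      # n x q posterior responsibilities
    loglik_trace: np.ndarray


def nl_em_fit(
    net: Network,
    q: int,
    seed: int = 0,
    max_iters: int = 200,
    tol: float = 1e-8,
    binary: bool = True,
) -> MixtureParams:
    """EM fit of the node-class mixture model.

    E-step: responsibility of class r for node i proportional to
    ``pi_r prod_j theta_rj^{A_ij}`` (computed in log space).  M-step:
    ``pi_r = mean_i resp_ir`` and ``theta_rj propto sum_i resp_ir A_ij``.
    Stops when the log-likelihood improves by less than ``tol`` or after
    ``max_iters`` iterations.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    if q > net.n:
        raise ValueError(f"q={q} exceeds node count {net.n}")
    A = _adjacency(net, binary)
    n = net.n
    rng = np.random.default_rng(seed)

    # random soft start: perturbed-uniform responsibilities
    resp = rng.uniform(0.75, 1.25, size=(n, q))
    resp /= resp.sum(axis=1, keepdims=True)

    degrees = A.sum(axis=1)
    trace = []
    loglik = -np.inf
    for _ in range(max_iters):
        # M-step from current responsibilities
        pi = resp.mean(axis=0)
        num = resp.T @ A  # q x n
        theta = num / np.maximum(num.sum(axis=1, keepdims=True), _EPS)
        # E-step / log-likelihood
        log_theta = np.log(np.maximum(theta, _EPS))
        log_w = np.log(np.maximum(pi, _EPS))[None, :] + A @ log_theta.T  # n x q
        norm = logsumexp(log_w, axis=1)
        new_loglik = float(norm.sum())
        resp = np.exp(log_w - norm[:, None])
        trace.append(new_loglik)
        if new_loglik - loglik < tol and np.isfinite(loglik):
            loglik = new_loglik
            break
        loglik = new_loglik
    return MixtureParams(
        pi=pi, theta=theta, resp=resp, loglik_trace=np.asarray(trace)
    )


def nl_assign(params: MixtureParams) -> Assignment:
    """Each node gets the class with the highest posterior responsibility."""
    roles = np.argmax(params.resp, axis=1)
    return Assignment(roles, params.resp.shape[1])


def best_nmf_assignment(
    net: Network, q: int, n_seeds: int = 10, seed: int = 0, iters: int = 100
) -> Assignment:
    """Best-of-seeds NMF assignment, selected by lowest final KL divergence."""
    ss = np.random.SeedSequence(seed)
    best = None
    best_kl = np.inf
    for child in ss.spawn(n_seeds):
        f = nmf_fit(net, q, iters=iters, seed=int(child.generate_state(1)[0] % 2**31))
        if f.kl_trace[-1] < best_kl:
            best_kl = f.kl_trace[-1]
            best = f
    return nmf_assign(best)


def best_nl_assignment(
    net: Network, q: int, n_seeds: int = 10, seed: int = 0, max_iters: int = 200
) -> Assignment:
    """Best-of-seeds mixture assignment, selected by highest log-likelihood."""
    ss = np.random.SeedSequence(seed)
    best = None
    best_ll = -np.inf
    for child in ss.spawn(n_seeds):
        p = nl_em_fit(
            net, q, seed=int(child.generate_state(1)[0] % 2**31), max_iters=max_iters
        )
        if p.loglik_trace[-1] > best_ll:
            best_ll = p.loglik_trace[-1]
            best = p
    return nl_assign(best)
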