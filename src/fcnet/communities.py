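"""Overlapping community detection by Poisson non-negative matrix factorization.

A non-negative connectivity matrix A is factorized as A ~ P Q with
P (N x K) and Q (K x N) non-negative.  Each edge weight is modelled as a
Poisson count with rate sum_k P_ik Q_kj; multiplicative updates

    Q <- Q / (P^T 1 + B Q) * [P^T (A / PQ)]
    P <- P / (1 Q^T + P B) * [(A / PQ) Q^T]

descend the Kullback-Leibler (Poisson) divergence plus, when the diagonal
shrinkage matrix B is nonzero, a half-normal penalty sum_k beta_k/2
(||P_.k||^2 + ||Q_k.||^2) that biases superfluous communities towards
zero.  Column k of P scores each region's affinity for community k;
thresholding every column independently at its mean plus one standard
deviation yields *overlapping* communities — a region may clear several
columns' thresholds at once.

A disjoint Louvain modularity partition of the same adjacency matrix is
provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .matrices import AdjacencyMatrix, DegenerateInputError

__all__ = [
    "MembershipMatrix",
    "OverlappingCommunities",
    "Partition",
    "nmf_fit",
    "nmf_restarts",
    "canonicalize",
    "threshold_communities",
    "modularity_partition",
    "duplicate_communities",
]

_EPS = 1e-12


@dataclass
class MembershipMatrix:
    """Non-negative factors of the connectivity matrix and their fit trace."""

    P: np.ndarray
    Q: np.ndarray
    K: int
    beta_diag: np.ndarray
    cost_trace: list = field(default_factory=list)
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.beta_diag = np.asarray(self.beta_diag, dtype=float)
        if np.any(self.P < 0) or np.any(self.Q < 0):
            raise ValueError("membership factors must be non-negative")
        if self.K > self.P.shape[0]:
            raise ValueError("community count K cannot exceed region count N")

    @property
    def final_cost(self) -> float:
        return self.cost_trace[-1] if self.cost_trace else np.inf


@dataclass
class OverlappingCommunities:
    """K region sets (possibly intersecting) plus the per-column cutoffs used."""

    communities: list          # list of K sets of 0-based region indices
    thresholds: np.ndarray
    labels: list = field(default_factory=list)

    def member_labels(self) -> list:
        if not self.labels:
            return [sorted(c) for c in self.communities]
        return [[self.labels[i] for i in sorted(c)] for c in self.communities]


@dataclass
class Partition:
    """Disjoint assignment of every region to exactly one module (ids 1..N_m)."""

    assignment: dict           # region index -> module id
    n_modules: int

    def __post_init__(self):
        mods = set(self.assignment.values())
        if mods != set(range(1, self.n_modules + 1)):
            raise ValueError("module ids must be contiguous 1..N_m")

    def modules(self) -> list:
        out = [set() for _ in range(self.n_modules)]
        for node, mod in self.assignment.items():
            out[mod - 1].add(node)
        return out


def _as_array(a) -> tuple:
    if isinstance(a, AdjacencyMatrix):
        return a.values, list(a.labels)
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("input matrix must be square")
    return arr, []


def _kl_cost(a: np.ndarray, p: np.ndarray, q: np.ndarray,
             beta: np.ndarray) -> float:
    rec = np.maximum(p @ q, _EPS)
    pos = a > 0
    cost = float(np.sum(a[pos] * np.log(a[pos] / rec[pos])) - a.sum() + rec.sum())
    if np.any(beta > 0):
        cost += 0.5 * float(np.sum(beta * ((p * p).sum(axis=0) + (q * q).sum(axis=1))))
    return cost


def nmf_fit(a, k: int, max_iterations: int = 100, seed: int = 0,
            beta_mode: str = "fixed", beta_value: float = 0.0,
            gamma_a: float = 5.0, gamma_b: float = 2.0) -> MembershipMatrix:
    """Fit the Poisson NMF by multiplicative updates.

    ``a`` may be an :class:`AdjacencyMatrix` or any square non-negative
    array.  Factors are initialized uniformly on [0, 1].  ``beta_mode``
    'fixed' keeps every shrinkage hyper-parameter at ``beta_value`` (0 gives
    plain KL-NMF); 'gamma_update' re-estimates beta_k each sweep from a
    Gamma(a, b) hyper-prior as beta_k = (2N + a - 1) /
    (0.5 (||P_.k||^2 + ||Q_k.||^2) + b).
    """
    av, labels = _as_array(a)
    n = av.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"community count K must satisfy 1 <= K <= N, got K={k}, N={n}")
    if np.any(av < 0):
        raise ValueError("NMF input must be non-negative")
    if beta_mode not in ("fixed", "gamma_update"):
        raise ValueError("beta_mode must be 'fixed' or 'gamma_update'")

    rng = np.random.default_rng(seed)
    p = rng.uniform(size=(n, k))
    q = rng.uniform(size=(k, n))
    beta = np.full(k, float(beta_value))

    trace = [_kl_cost(av, p, q, beta)]
    for _ in range(max_iterations):
        ratio = av / np.maximum(p @ q, _EPS)
        denom_q = p.sum(axis=0)[:, None] + beta[:, None] * q
        q = q * (p.T @ ratio) / np.maximum(denom_q, _EPS)

        ratio = av / np.maximum(p @ q, _EPS)
        denom_p = q.sum(axis=1)[None, :] + p * beta[None, :]
        p = p * (ratio @ q.T) / np.maximum(denom_p, _EPS)

        if beta_mode == "gamma_update":
            scale = 0.5 * ((p * p).sum(axis=0) + (q * q).sum(axis=1)) + gamma_b
            beta = (2.0 * n + gamma_a - 1.0) / scale
        trace.append(_kl_cost(av, p, q, beta))

    return MembershipMatrix(p, q, k, beta, trace, labels)


def _canonical_order(p: np.ndarray) -> np.ndarray:
    """Column order: descending column sum, ties by original column index."""
    sums = p.sum(axis=0)
    return np.argsort(-sums, kind="stable")


def canonicalize(m: MembershipMatrix) -> MembershipMatrix:
    """Remove the two gauge freedoms of the factorization.

    Each component k is rescaled so ||P_.k|| = ||Q_k.|| (the product PQ is
    unchanged), then columns of P and the matching rows of Q are reordered
    by descending column sum of P.  Restarts that converge to the same
    reconstruction up to scaling and community permutation become
    numerically comparable.
    """
    p, q = m.P.copy(), m.Q.copy()
    pn = np.linalg.norm(p, axis=0)
    qn = np.linalg.norm(q, axis=1)
    scale = np.sqrt(np.maximum(qn, _EPS) / np.maximum(pn, _EPS))
    p *= scale[None, :]
    q /= scale[:, None]
    order = _canonical_order(p)
    return MembershipMatrix(p[:, order], q[order, :], m.K,
                            m.beta_diag[order], m.cost_trace, m.labels)


def nmf_restarts(a, k: int, restarts: int = 10, base_seed: int = 0,
                 **fit_kwargs) -> MembershipMatrix:
    """Run :func:`nmf_fit` from ``restarts`` random initializations.

    Seeds base_seed .. base_seed+restarts-1; the run with lowest final cost
    wins and is returned in canonical form (see :func:`canonicalize`).
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    best = None
    for r in range(restarts):
        m = nmf_fit(a, k, seed=base_seed + r, **fit_kwargs)
        if best is None or m.final_cost < best.final_cost:
            best = m
    return canonicalize(best)


def threshold_communities(m: MembershipMatrix,
                          rule: str = "mean_plus_std",
                          ddof: int = 1) -> OverlappingCommunities:
    """Per-column thresholding of P into overlapping region sets.

    Each community k keeps the regions whose loading strictly exceeds
    mean(P[:, k]) + std(P[:, k]) (sample std, denominator N-1 by default).
    A constant column therefore yields an empty community.
    """
    if rule != "mean_plus_std":
        raise ValueError(f"unknown thresholding rule {rule!r}")
    tau = m.P.mean(axis=0) + m.P.std(axis=0, ddof=ddof)
    comms = [set(np.flatnonzero(m.P[:, k] > tau[k]).tolist()) for k in range(m.K)]
    return OverlappingCommunities(comms, tau, list(m.labels))


def duplicate_communities(m: MembershipMatrix, tol: float = 0.05) -> list:
    """Pairs of near-identical P columns — a symptom of choosing K too large.

    Columns i < j are flagged when ||P_i - P_j|| <= tol * max(||P_i||, ||P_j||).
    """
    pairs = []
    for i in range(m.K):
        for j in range(i + 1, m.K):
            scale = max(np.linalg.norm(m.P[:, i]), np.linalg.norm(m.P[:, j]), _EPS)
            if np.linalg.norm(m.P[:, i] - m.P[:, j]) <= tol * scale:
                pairs.append((i, j))
    return pairs


def modularity_partition(a, seed: int = 0, resolution: float = 1.0,
                         restarts: int = 10) -> Partition:
    """Disjoint Louvain modularity partition of a weighted adjacency matrix.

    Louvain's greedy node sweep can stall in a local optimum, so the
    algorithm is run from ``restarts`` seeded sweep orders (seed ..
    seed+restarts-1) and the partition with highest modularity wins —
    the usual practice when Louvain is used as a modularity maximizer.
    Module ids are renumbered 1..N_m in order of each module's smallest
    region index, so the labelling is deterministic given the seed.
    """
    av, _labels = _as_array(a)
    if np.max(av, initial=0.0) <= 0.0:
        raise DegenerateInputError("adjacency matrix has no positive edge")
    n = av.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(av, 1))
    g.add_weighted_edges_from((int(i), int(j), float(av[i, j])) for i, j in zip(ii, jj))
    best, best_q = None, -np.inf
    for r in range(max(1, restarts)):
        comms = nx.community.louvain_communities(g, weight="weight",
                                                 seed=seed + r,
                                                 resolution=resolution)
        q = nx.community.modularity(g, comms, weight="weight",
                                    resolution=resolution)
        if q > best_q:
            best, best_q = comms, q
    comms = sorted((sorted(c) for c in best), key=lambda c: c[0])
    assignment = {node: mod + 1 for mod, members in enumerate(comms) for node in members}
    return Partition(assignment, len(comms))
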