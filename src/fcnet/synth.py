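"""Synthetic benchmarks with planted overlapping community structure.

Region time-series are generated from K latent community signals: region i
observes the sum of the signals of every community it belongs to, plus
white Gaussian noise.  Membership is a binary N x K matrix whose rows may
carry several ones — those regions are the planted *overlap* and should be
recovered in more than one community by the detection pipeline.  Latent
signals are white by default; an optional AR(1) coefficient adds the
temporal smoothness typical of haemodynamic signals, which does not change
the covariance structure the estimators consume in any essential way.

Adjacency matrices can also be planted directly (within/between community
weight levels with a small seeded jitter) to exercise the community stage
in isolation, and ``score_recovery`` measures recovered-vs-planted
agreement by greedy best-match Jaccard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .communities import OverlappingCommunities
from .matrices import AdjacencyMatrix, ConfigError, TimeSeriesMatrix

__all__ = [
    "SyntheticSpec",
    "planted_membership",
    "generate_timeseries",
    "generate_adjacency",
    "score_recovery",
]


def planted_membership(n_regions: int = 30, n_communities: int = 3,
                       overlaps_per_pair: int = 2) -> np.ndarray:
    """Deterministic binary membership with planted overlap.

    The first ``overlaps_per_pair`` * C(K,2) regions each belong to one
    distinct pair of communities; the remaining regions are dealt out
    round-robin as single-membership members.
    """
    k = n_communities
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    n_overlap = overlaps_per_pair * len(pairs)
    if n_overlap + 2 * k > n_regions:
        raise ConfigError("not enough regions for the requested overlap structure")
    m = np.zeros((n_regions, k), dtype=int)
    r = 0
    for pair in pairs:
        for _ in range(overlaps_per_pair):
            m[r, list(pair)] = 1
            r += 1
    for i, row in enumerate(range(r, n_regions)):
        m[row, i % k] = 1
    return m


@dataclass
class SyntheticSpec:
    """Parameters of the planted-community generator."""

    n_regions: int = 30
    n_times: int = 300
    n_communities: int = 3
    membership: np.ndarray | None = None
    signal_sd: float = 1.0
    noise_sd: float = 0.3
    seed: int = 0
    ar_coeff: float = 0.0
    labels: list = field(default_factory=list)

    def __post_init__(self):
        if self.membership is None:
            self.membership = planted_membership(self.n_regions, self.n_communities)
        self.membership = np.asarray(self.membership, dtype=int)
        if self.membership.shape != (self.n_regions, self.n_communities):
            raise ConfigError("membership must be an N x K binary matrix")
        if not np.isin(self.membership, (0, 1)).all():
            raise ConfigError("membership entries must be 0/1")
        sizes = self.membership.sum(axis=0)
        if np.any(sizes < 2):
            raise ConfigError("every community needs at least 2 member regions")
        if self.signal_sd <= 0:
            raise ConfigError("signal_sd must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not -1 < self.ar_coeff < 1:
            raise ConfigError("ar_coeff must lie in (-1, 1)")
        if not self.labels:
            self.labels = [f"R{i + 1}" for i in range(self.n_regions)]

    @property
    def true_communities(self) -> list:
        return [set(np.flatnonzero(self.membership[:, k]).tolist())
                for k in range(self.n_communities)]


def generate_timeseries(spec: SyntheticSpec):
    """Draw (TimeSeriesMatrix, membership ground truth) from the spec.

    Latent signals s_k(t) ~ N(0, signal_sd^2) i.i.d. (optionally AR(1) with
    matched stationary variance); region i = sum_k membership_ik s_k + noise.
    Bit-identical under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    t, n, k = spec.n_times, spec.n_regions, spec.n_communities
    innov = rng.normal(0.0, spec.signal_sd, size=(t, k))
    if spec.ar_coeff:
        phi = spec.ar_coeff
        signals = np.empty_like(innov)
        scale = np.sqrt(1.0 - phi * phi)  # keep stationary variance = signal_sd^2
        signals[0] = innov[0]
        for tt in range(1, t):
            signals[tt] = phi * signals[tt - 1] + scale * innov[tt]
    else:
        signals = innov
    noise = rng.normal(0.0, spec.noise_sd, size=(t, n)) if spec.noise_sd else 0.0
    x = signals @ spec.membership.T + noise
    return TimeSeriesMatrix(x, list(spec.labels)), spec.membership.copy()


def generate_adjacency(spec: SyntheticSpec, within_weight: float = 1.0,
                       between_weight: float = 0.05, jitter: float = 0.05):
    """Plant an adjacency matrix directly from the membership structure.

    Regions sharing at least one community are linked at ``within_weight``,
    all other pairs at ``between_weight``; a seeded multiplicative jitter of
    +/- ``jitter`` breaks ties.  Returns (AdjacencyMatrix, membership).
    """
    if not within_weight > between_weight >= 0:
        raise ConfigError("require within_weight > between_weight >= 0")
    rng = np.random.default_rng(spec.seed)
    shared = (spec.membership @ spec.membership.T) > 0
    a = np.where(shared, within_weight, between_weight).astype(float)
    n = spec.n_regions
    jit = rng.uniform(-jitter, jitter, size=(n, n))
    jit = np.triu(jit, 1)
    a = a * (1.0 + jit + jit.T)
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(a, list(spec.labels)), spec.membership.copy()


def _jaccard(s1: set, s2: set) -> float:
    union = s1 | s2
    if not union:
        return 0.0
    return len(s1 & s2) / len(union)


def score_recovery(found, truth) -> float:
    """Greedy best-match mean Jaccard between found and planted communities.

    True communities (columns of the membership matrix, taken in order) each
    claim their highest-Jaccard found community without replacement; the
    score is the mean Jaccard over true communities, in [0, 1].
    """
    if isinstance(found, OverlappingCommunities):
        found_sets = [set(c) for c in found.communities]
    else:
        found_sets = [set(c) for c in found]
    truth = np.asarray(truth)
    true_sets = [set(np.flatnonzero(truth[:, k]).tolist()) for k in range(truth.shape[1])]
    n_true = max((max(s) for s in true_sets if s), default=-1)
    n_found = max((max(s) for s in found_sets if s), default=-1)
    if n_found > truth.shape[0] - 1 or n_true > truth.shape[0] - 1:
        raise ValueError("found community indices exceed the planted region count")

    available = list(range(len(found_sets)))
    scores = []
    for ts in true_sets:
        if not available:
            scores.append(0.0)
            continue
        best = max(available, key=lambda j: (_jaccard(ts, found_sets[j]), -j))
        scores.append(_jaccard(ts, found_sets[best]))
        available.remove(best)
    return float(np.mean(scores)) if scores else 0.0
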