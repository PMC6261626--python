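"""Independent oracles used by the test suite.

Each oracle deliberately takes a different algorithmic route from the
implementation it checks: a Davis-Yin three-operator-splitting solver for
the penalized regression objectives, brute-force enumeration of simple
paths for betweenness, and exhaustive enumeration of set partitions for
modularity.  None of them share solver code with the package.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


# ---------------------------------------------------------------------------
# Generic convex-solver oracle: Davis-Yin splitting for
#   min_W  0.5||X - XW||_F^2 + l1 * ||W||_1 + nuc * ||W||_*
#          (+ frob/2 ||W||_F^2)   s.t. diag(W) = 0
# ---------------------------------------------------------------------------

def _prox_l1_diag0(v: np.ndarray, t: float) -> np.ndarray:
    out = np.sign(v) * np.maximum(0.0, np.abs(v) - t)
    np.fill_diagonal(out, 0.0)
    return out


def _prox_nuclear(v: np.ndarray, t: float) -> np.ndarray:
    u, s, vt = np.linalg.svd(v, full_matrices=False)
    return (u * np.maximum(0.0, s - t)) @ vt


def dys_objective(x: np.ndarray, w: np.ndarray, l1: float, nuc: float,
                  frob: float = 0.0) -> float:
    r = x - x @ w
    obj = 0.5 * np.sum(r * r) + l1 * np.abs(w).sum()
    if nuc:
        obj += nuc * np.linalg.svd(w, compute_uv=False).sum()
    if frob:
        obj += 0.5 * frob * np.sum(w * w)
    return float(obj)


def dys_solve(x: np.ndarray, l1: float, nuc: float, frob: float = 0.0,
              max_iter: int = 50000, tol: float = 1e-13):
    """Davis-Yin splitting; returns (W, objective at W).

    f = smooth data-fit (+ ridge), g = l1 + diagonal constraint (exact
    separable prox), h = nuclear norm (SVT prox).  Step 1/L with L the
    largest eigenvalue of X^T X (+ frob).
    """
    g = x.T @ x
    n = g.shape[0]
    lip = float(np.linalg.eigvalsh(g).max()) + frob
    gamma = 1.0 / lip
    z = np.zeros((n, n))
    w = z
    for it in range(max_iter):
        w = _prox_l1_diag0(z, gamma * l1)
        grad = g @ w - g + frob * w
        xh = _prox_nuclear(2.0 * w - z - gamma * grad, gamma * nuc)
        step = xh - w
        z = z + step
        if it % 50 == 0 and np.linalg.norm(step) < tol * max(1.0, np.linalg.norm(w)):
            break
    return w, dys_objective(x, w, l1, nuc, frob)


# ---------------------------------------------------------------------------
# Exhaustive betweenness oracle: enumerate all simple paths per ordered pair
# ---------------------------------------------------------------------------

def brute_betweenness(a: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Ordered-pair betweenness by enumerating every simple path.

    Edge lengths are 1/weight; for each ordered (s, t) the geodesics are the
    simple paths of minimal total length (ties within ``tol`` relative), and
    every interior node of a geodesic collects 1/#geodesics.
    """
    n = a.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if a[i, j] > 0:
                g.add_edge(i, j, length=1.0 / a[i, j])
    score = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = list(nx.all_simple_paths(g, s, t))
            if not paths:
                continue
            lengths = [sum(g[u][v]["length"] for u, v in zip(p, p[1:])) for p in paths]
            best = min(lengths)
            geos = [p for p, l in zip(paths, lengths) if l <= best * (1 + tol)]
            for p in geos:
                for v in p[1:-1]:
                    score[v] += 1.0 / len(geos)
    return score


# ---------------------------------------------------------------------------
# Exhaustive modularity oracle: enumerate all set partitions
# ---------------------------------------------------------------------------

def _set_partitions(items):
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1:]
        yield [[first]] + smaller


def best_modularity(a: np.ndarray) -> float:
    """Maximum Newman-Girvan modularity over every partition of the nodes."""
    n = a.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if a[i, j] > 0:
                g.add_edge(i, j, weight=float(a[i, j]))
    best = -np.inf
    for part in _set_partitions(list(range(n))):
        q = nx.community.modularity(g, [set(b) for b in part], weight="weight")
        best = max(best, q)
    return best


def modularity_of(a: np.ndarray, communities) -> float:
    n = a.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if a[i, j] > 0:
                g.add_edge(i, j, weight=float(a[i, j]))
    return nx.community.modularity(g, [set(c) for c in communities], weight="weight")


# ---------------------------------------------------------------------------
# Random test instances
# ---------------------------------------------------------------------------

def random_instance(seed: int, t: int = 20, n: int = 5) -> np.ndarray:
    """Unit-normalized random time-series matrix with mild correlation."""
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=(t, max(2, n // 2)))
    mix = rng.normal(size=(max(2, n // 2), n))
    x = latent @ mix + 0.5 * rng.normal(size=(t, n))
    return x / np.linalg.norm(x, axis=0)
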