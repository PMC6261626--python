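"""Weighted graph measures: degree, participation coefficient, betweenness.

Degree is the weighted row sum D_i = sum_j A_ij.  The participation
coefficient of node i under a disjoint partition into N_m modules is

    P_i = 1 - sum_s (D_is / D_i)^2,     D_is = sum_{j in s} A_ij,

zero when all of a node's weight stays inside one module and approaching
1 - 1/N_m when spread evenly.  Betweenness centrality counts, for every
ordered source-target pair, the fraction of shortest paths through a node;
edge weights are interpreted as capacities, so path length accumulates
1/weight per hop (strong edges are short).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .communities import Partition
from .matrices import AdjacencyMatrix

__all__ = [
    "NodeMetrics",
    "degree",
    "participation_coefficient",
    "betweenness_centrality",
    "node_metrics",
]


@dataclass
class NodeMetrics:
    degree: np.ndarray
    participation: np.ndarray
    betweenness: np.ndarray
    mean_betweenness: float
    labels: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"degree": self.degree, "participation": self.participation,
             "betweenness": self.betweenness},
            index=pd.Index(self.labels, name="region"),
        )


def _values(a) -> np.ndarray:
    return a.values if isinstance(a, AdjacencyMatrix) else np.asarray(a, dtype=float)


def degree(a) -> np.ndarray:
    """Weighted degree: row sums of the adjacency matrix."""
    return _values(a).sum(axis=1)


def participation_coefficient(a, part: Partition) -> np.ndarray:
    av = _values(a)
    n = av.shape[0]
    missing = [i for i in range(n) if i not in part.assignment]
    if missing:
        raise ValueError(f"partition is missing nodes {missing[:5]}; participation undefined")
    deg = av.sum(axis=1)
    pc = np.zeros(n)
    module_masks = [
        np.fromiter((part.assignment[j] == m for j in range(n)), dtype=bool, count=n)
        for m in range(1, part.n_modules + 1)
    ]
    for i in range(n):
        if deg[i] <= 0:
            continue  # isolated node: participation defined as 0
        shares = np.array([av[i, mask].sum() / deg[i] for mask in module_masks])
        pc[i] = 1.0 - float(np.sum(shares ** 2))
    return pc


def betweenness_centrality(a, normalized: bool = False) -> np.ndarray:
    """Weighted betweenness, ordered-pair (raw Brandes) convention.

    Scores sum sigma_st(v)/sigma_st over all ordered pairs s != t != v on
    shortest paths measured with lengths 1/weight (zero weight = no edge).
    With ``normalized`` the raw counts are divided by (N-1)(N-2), the number
    of ordered pairs, giving the fraction-of-geodesics reading.
    """
    av = _values(a)
    n = av.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(av, 1))
    g.add_edges_from(
        (int(i), int(j), {"length": 1.0 / float(av[i, j])}) for i, j in zip(ii, jj)
    )
    # networkx returns the unordered-pair sum for undirected graphs; double it.
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    raw = 2.0 * np.array([bc[i] for i in range(n)])
    if normalized:
        raw = raw / ((n - 1) * (n - 2)) if n > 2 else np.zeros(n)
    return raw


def node_metrics(a, part: Partition, normalized_bc: bool = False) -> NodeMetrics:
    """Per-node degree / participation / betweenness table for one network."""
    labels = a.labels if isinstance(a, AdjacencyMatrix) else [
        f"R{i + 1}" for i in range(_values(a).shape[0])
    ]
    bc = betweenness_centrality(a, normalized=normalized_bc)
    return NodeMetrics(
        degree=degree(a),
        participation=participation_coefficient(a, part),
        betweenness=bc,
        mean_betweenness=float(bc.mean()),
        labels=list(labels),
    )
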