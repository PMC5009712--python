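"""Lagged spatial autocorrelation of an areal covariate on a neighbour graph.

Small-area covariates such as deprivation deciles are typically spatially
clustered; this module quantifies that clustering as a function of
neighbourhood separation.  Areas are linked into a symmetric k-nearest-
neighbour graph on their centroids, pairs of areas are stratified by graph
shortest-path distance ("lag" h: direct neighbours at lag 1,
neighbours-of-neighbours at lag 2, ...), and two statistics are computed per
lag: Moran's I with binary lag-specific weights, and the Pearson
autocorrelation of the lag-h value pairs (the standard correlogram).
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import as_coords

__all__ = [
    "LagStatistic",
    "build_knn_graph",
    "correlogram",
    "lag_pairs",
    "lagged_moran_i",
]


def build_knn_graph(centroids, k: int = 6) -> nx.Graph:
    """Symmetrised k-nearest-neighbour graph on area centroids.

    An edge is kept when either endpoint selects the other among its k
    nearest centroids (by L2), giving a symmetric graph with no self-loops.
    The default k = 6 is a common contiguity surrogate for irregular areal
    units.  Ties between equidistant or duplicate centroids are broken by
    index order (the kd-tree's stable ordering).
    """
    coords = as_coords(centroids)
    n = len(coords)
    if k < 1:
        raise ValueError("k must be at least 1")
    if k >= n:
        raise ValueError(f"k = {k} requires at least k+1 = {k + 1} centroids, got {n}")
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)  # self is always among the k+1
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i]:
            if j != i:
                graph.add_edge(i, int(j))
    return graph


def lag_pairs(graph: nx.Graph, h: int) -> set[tuple]:
    """Unordered node pairs at graph shortest-path distance exactly h.

    Pairs in different components never appear at any lag.  Over all h the
    lag sets partition the connected pairs.
    """
    if h < 1:
        raise ValueError("lag must be at least 1")
    pairs = set()
    for source, dists in nx.all_pairs_shortest_path_length(graph, cutoff=h):
        for target, d in dists.items():
            if d == h and source < target:
                pairs.add((source, target))
    return pairs


@dataclasses.dataclass(frozen=True)
class LagStatistic:
    """Moran's I and Pearson autocorrelation at one neighbourhood lag."""

    lag: int
    moran_i: float
    autocorr: float
    n_pairs: int


def lagged_moran_i(values, graph: nx.Graph, h: int,
                   row_standardised: bool = False,
                   _pairs: set | None = None) -> LagStatistic:
    """Moran's I at lag h with binary lag-specific weights.

    With w_ij = 1 for ordered pairs (i, j) at shortest-path distance exactly
    h and z the mean-centred values:

        I = (n / sum w_ij) * sum_ij w_ij z_i z_j / sum_i z_i^2

    ``autocorr`` is the Pearson correlation over the ordered lag-h pair
    list, i.e. the classic correlogram coefficient.  With
    ``row_standardised=True`` each ordered weight is divided by the lag-h
    degree of its source node before the Moran sum.
    """
    v = np.asarray(values, dtype=float)
    n = graph.number_of_nodes()
    if len(v) != n:
        raise ValueError("values must align with graph nodes 0..n-1")
    if np.var(v) == 0:
        raise ValueError("values have zero variance; Moran's I is undefined")
    pairs = lag_pairs(graph, h) if _pairs is None else _pairs
    if not pairs:
        raise ValueError(f"no node pairs at lag {h}; statistic undefined")
    i_idx = np.fromiter((p[0] for p in sorted(pairs)), dtype=np.int64, count=len(pairs))
    j_idx = np.fromiter((p[1] for p in sorted(pairs)), dtype=np.int64, count=len(pairs))
    z = v - v.mean()
    if row_standardised:
        deg = np.zeros(n)
        np.add.at(deg, i_idx, 1.0)
        np.add.at(deg, j_idx, 1.0)
        w = 1.0 / deg[i_idx] + 1.0 / deg[j_idx]  # both orderings of each pair
    else:
        w = np.full(len(pairs), 2.0)  # binary weights, both orderings
    cross = float(np.sum(w * z[i_idx] * z[j_idx]))
    moran = (n / float(w.sum())) * cross / float(np.sum(z ** 2))
    # correlogram: Pearson correlation over the ordered pair list (both
    # directions, so the coefficient is symmetric in the pair ordering)
    a = np.concatenate([v[i_idx], v[j_idx]])
    b = np.concatenate([v[j_idx], v[i_idx]])
    autocorr = float(np.corrcoef(a, b)[0, 1])
    return LagStatistic(lag=h, moran_i=moran, autocorr=autocorr, n_pairs=len(pairs))


def correlogram(values, graph: nx.Graph, max_lag: int,
                row_standardised: bool = False) -> pd.DataFrame:
    """Lag-by-statistic table for lags 1..max_lag (lags with no pairs are skipped)."""
    rows = []
    for h in range(1, max_lag + 1):
        pairs = lag_pairs(graph, h)
        if not pairs:
            continue
        stat = lagged_moran_i(values, graph, h, row_standardised=row_standardised,
                              _pairs=pairs)
        rows.append(dataclasses.asdict(stat))
    return pd.DataFrame(rows, columns=["lag", "moran_i", "autocorr", "n_pairs"])
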