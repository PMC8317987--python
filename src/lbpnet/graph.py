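"""Density thresholding and binary local graph metrics.

An FC matrix is reduced to an undirected binary graph by keeping the k
strongest positive edges, where k = round(density * N(N-1)/2). Four local
metrics are computed per node — degree centrality (DC), clustering
coefficient (CC), betweenness centrality (BC), local efficiency (LE) — and
averaged across a grid of densities so that no single arbitrary threshold
drives group comparisons.

Conventions (Brain Connectivity Toolbox style):
  * BC is unnormalized, each unordered pair (s, t) counted once; pairs with
    no connecting path contribute 0.
  * CC(i) = 0 and LE(i) = 0 when degree(i) < 2.
  * LE(i) is the mean of 1/d(j, k) over ordered neighbor pairs of i, with
    distances measured inside the subgraph induced on the neighbors;
    unreachable pairs contribute 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import FCMatrix

__all__ = [
    "DEFAULT_DENSITIES",
    "BinaryGraph",
    "threshold_by_density",
    "degree_centrality",
    "clustering_coefficient",
    "betweenness_centrality",
    "local_efficiency",
    "metrics_across_densities",
    "METRIC_NAMES",
]

#: 15% to 30% in steps of 2.5%
DEFAULT_DENSITIES: tuple[float, ...] = (0.150, 0.175, 0.200, 0.225, 0.250, 0.275, 0.300)

METRIC_NAMES: tuple[str, ...] = ("DC", "CC", "BC", "LE")


@dataclass
class BinaryGraph:
    """Symmetric 0/1 adjacency with zero diagonal at a given edge density."""

    adjacency: np.ndarray
    density: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def _as_adjacency(g: BinaryGraph | np.ndarray) -> np.ndarray:
    if isinstance(g, BinaryGraph):
        return g.adjacency
    return BinaryGraph(np.asarray(g), density=float("nan")).adjacency


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def threshold_by_density(
    fc: FCMatrix | np.ndarray, density: float
) -> BinaryGraph:
    """Keep the k strongest off-diagonal edges by signed Fisher-z weight.

    k = round(density * N(N-1)/2), half-up. Ties at the cutoff are broken
    deterministically by ascending (i, j) lexicographic edge index so that
    repeated runs and platform changes give identical graphs.
    """
    values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    n = values.shape[0]
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must lie in (0, 1], got {density}")
    e_max = n * (n - 1) // 2
    k = _round_half_up(density * e_max)
    if k == 0:
        raise ValueError(
            f"density {density} retains zero of {e_max} possible edges"
        )
    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    # lexsort: last key is primary -> order by descending weight, then (i, j)
    order = np.lexsort((ju, iu, -w))
    keep = order[:k]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return BinaryGraph(adjacency=adj, density=density)


def degree_centrality(g: BinaryGraph | np.ndarray) -> np.ndarray:
    """Number of edges incident to each node."""
    return _as_adjacency(g).sum(axis=1).astype(float)


def clustering_coefficient(g: BinaryGraph | np.ndarray) -> np.ndarray:
    """Fraction of each node's neighbor pairs that are themselves connected."""
    a = _as_adjacency(g).astype(float)
    deg = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return cc


def betweenness_centrality(g: BinaryGraph | np.ndarray) -> np.ndarray:
    """Unnormalized shortest-path betweenness, unordered pairs counted once.

    Brandes accumulation over BFS shortest-path DAGs, vectorized across all
    sources: shortest-path counts sigma[s, v] are built level by level from
    the BFS distance matrix, then dependencies delta[s, v] are accumulated
    from the deepest level inward. Disconnected pairs contribute nothing.
    """
    a = _as_adjacency(g).astype(float)
    n = a.shape[0]
    d = shortest_path(csr_matrix(a), method="D", unweighted=True)
    finite = np.isfinite(d)
    max_level = int(d[finite].max()) if finite.any() else 0
    # sigma[s, v]: number of shortest s->v paths
    sigma = np.eye(n)
    for lev in range(1, max_level + 1):
        at_prev = np.where(d == lev - 1, sigma, 0.0)
        sigma += (at_prev @ a) * (d == lev)
    # delta[s, v]: Brandes dependency of source s on v
    delta = np.zeros((n, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_sigma = np.where(sigma > 0, 1.0 / sigma, 0.0)
    for lev in range(max_level - 1, 0, -1):
        downstream = np.where(d == lev + 1, (1.0 + delta) * inv_sigma, 0.0)
        delta += (downstream @ a) * sigma * (d == lev)
    bc = delta.sum(axis=0)
    return bc / 2.0  # each unordered (s, t) pair counted from both ends


def _bfs_all_pairs(sub: np.ndarray) -> np.ndarray:
    """All-pairs hop distances of a small dense 0/1 adjacency via level-wise
    boolean matrix products; unreachable pairs stay at +inf."""
    k = sub.shape[0]
    d = np.where(sub > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    reach = sub.astype(bool) | np.eye(k, dtype=bool)
    frontier = sub.astype(bool)
    lev = 1
    while frontier.any() and lev < k:
        lev += 1
        nxt = (frontier @ sub.astype(bool)) & ~reach
        d[nxt] = lev
        reach |= nxt
        frontier = nxt
    return d


def local_efficiency(g: BinaryGraph | np.ndarray) -> np.ndarray:
    """Global efficiency of each node's neighbor-induced subgraph."""
    a = _as_adjacency(g)
    n = a.shape[0]
    le = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        k = nb.size
        if k < 2:
            continue
        d = _bfs_all_pairs(a[np.ix_(nb, nb)])
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        le[i] = inv.sum() / (k * (k - 1))
    return le


_METRIC_FUNCS = {
    "DC": degree_centrality,
    "CC": clustering_coefficient,
    "BC": betweenness_centrality,
    "LE": local_efficiency,
}


def metrics_across_densities(
    fc: FCMatrix | np.ndarray,
    densities: tuple[float, ...] = DEFAULT_DENSITIES,
    metrics: tuple[str, ...] = METRIC_NAMES,
) -> pd.DataFrame:
    """Threshold at each density, compute metrics, average across densities.

    Returns a nodes-by-metrics DataFrame indexed by node id.
    """
    densities = tuple(densities)
    if not densities:
        raise ValueError("density grid is empty")
    if any(d2 <= d1 for d1, d2 in zip(densities, densities[1:])):
        raise ValueError("densities must be strictly increasing")
    unknown = set(metrics) - set(_METRIC_FUNCS)
    if unknown:
        raise ValueError(f"unknown metric(s): {sorted(unknown)}")
    node_ids = (
        fc.node_ids
        if isinstance(fc, FCMatrix)
        else np.arange(np.asarray(fc).shape[0])
    )
    acc = {m: None for m in metrics}
    for d in densities:
        graph = threshold_by_density(fc, d)
        for m in metrics:
            vals = _METRIC_FUNCS[m](graph)
            acc[m] = vals if acc[m] is None else acc[m] + vals
    out = pd.DataFrame(
        {m: acc[m] / len(densities) for m in metrics}, index=pd.Index(node_ids, name="node_id")
    )
    return out
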