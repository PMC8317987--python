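"""Independent brute-force oracles for tiny graphs and p-value procedures.

These deliberately avoid the package's own algorithms: betweenness is
computed by exhaustive simple-path enumeration, clustering by direct
triangle counting, distances by Floyd-Warshall, and the BH step-up rule by
a literal transcription of its definition.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def _all_shortest_paths(adj: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    """Every shortest simple path from s to t, by exhaustive DFS."""
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    if not np.isfinite(dist[s, t]):
        return []
    target = dist[s, t]
    paths = []

    def extend(path):
        v = path[-1]
        if v == t:
            if len(path) - 1 == target:
                paths.append(tuple(path))
            return
        if len(path) - 1 >= target:
            return
        for w in range(n):
            if adj[v, w] and w not in path:
                extend(path + [w])

    extend([s])
    return paths


def degree_oracle(adj: np.ndarray) -> np.ndarray:
    return adj.sum(axis=1).astype(float)


def clustering_oracle(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    cc = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        if nb.size < 2:
            continue
        links = sum(
            adj[u, v] for u, v in itertools.combinations(nb, 2)
        )
        cc[i] = 2.0 * links / (nb.size * (nb.size - 1))
    return cc


def betweenness_oracle(adj: np.ndarray) -> np.ndarray:
    """Unnormalized BC, each unordered pair once, via path enumeration."""
    n = adj.shape[0]
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def local_efficiency_oracle(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    le = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        k = nb.size
        if k < 2:
            continue
        d = floyd_warshall(adj[np.ix_(nb, nb)])
        tot = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and np.isfinite(d[a, b]):
                    tot += 1.0 / d[a, b]
        le[i] = tot / (k * (k - 1))
    return le


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values, literal step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(prev, p[idx] * m / rank_from_top)
        q[idx] = val
        prev = val
    return q


def random_graph(rng: np.random.Generator, n_max: int = 8) -> np.ndarray:
    n = int(rng.integers(2, n_max + 1))
    p = rng.uniform(0.1, 0.9)
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T
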