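"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid networkx and the package's own code paths:
betweenness is computed by exhaustively enumerating all geodesics with
BFS distances and recursive path expansion.
"""

from __future__ import annotations

import numpy as np


def bfs_distances(adj: np.ndarray, s: int) -> list[float]:
    n = len(adj)
    dist = [float("inf")] * n
    dist[s] = 0
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for v in range(n):
                if adj[u, v] and dist[v] == float("inf"):
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def all_geodesics(adj: np.ndarray, s: int, t: int) -> list[list[int]]:
    """Every shortest path from s to t, as node lists (empty if
    disconnected)."""
    dist = bfs_distances(adj, s)
    if dist[t] == float("inf"):
        return []
    paths: list[list[int]] = []

    def extend(path: list[int]) -> None:
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in range(len(adj)):
            if adj[u, v] and dist[v] == dist[u] + 1:
                extend(path + [v])

    extend([s])
    return paths


def brute_betweenness_pct(adj: np.ndarray) -> np.ndarray:
    """Normalized betweenness (percent) by exhaustive geodesic
    enumeration; pairs in different components contribute nothing."""
    n = len(adj)
    raw = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = all_geodesics(adj, s, t)
            if not paths:
                continue
            for i in range(n):
                if i in (s, t):
                    continue
                through = sum(1 for p in paths if i in p[1:-1])
                raw[i] += through / len(paths)
    return 100.0 * raw / ((n - 1) * (n - 2) / 2)


def random_symmetric_binary(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    m = (rng.random((n, n)) < p).astype(int)
    m = np.triu(m, 1)
    return m + m.T


def random_ordinal_matrix(
    n: int, max_level: int, rng: np.random.Generator, p_zero: float = 0.5
) -> np.ndarray:
    m = rng.integers(1, max_level + 1, size=(n, n))
    m[rng.random((n, n)) < p_zero] = 0
    np.fill_diagonal(m, 0)
    return m
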