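"""Independent brute-force implementations of every graph metric.

Deliberately naive (triple loops, explicit path enumeration) so they share
no code path with the package; used to verify the fast implementations on
small graphs.
"""

from __future__ import annotations

import numpy as np


def fw_distances(a: np.ndarray) -> np.ndarray:
    """Floyd-Warshall all-pairs shortest paths on a 0/1 adjacency matrix."""
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and a[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def clustering_per_node(a: np.ndarray) -> np.ndarray:
    """Fraction of connected neighbour pairs, by explicit pair enumeration."""
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for x in range(k) for y in range(x + 1, k)
            if a[nbrs[x], nbrs[y]]
        )
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def path_length(a: np.ndarray) -> float:
    """Mean finite off-diagonal shortest-path distance."""
    d = fw_distances(a)
    vals = [d[i, j] for i in range(len(a)) for j in range(len(a))
            if i != j and np.isfinite(d[i, j])]
    if not vals:
        raise ValueError("no reachable pairs")
    return float(np.mean(vals))


def global_efficiency(a: np.ndarray) -> float:
    d = fw_distances(a)
    n = len(a)
    total = sum(
        1.0 / d[i, j] for i in range(n) for j in range(n)
        if i != j and np.isfinite(d[i, j])
    )
    return total / (n * (n - 1)) if n > 1 else 0.0


def local_efficiency(a: np.ndarray) -> float:
    n = len(a)
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        total += global_efficiency(sub)
    return total / n


def nodal_efficiency(a: np.ndarray) -> np.ndarray:
    d = fw_distances(a)
    n = len(a)
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(
            1.0 / d[i, j] for j in range(n)
            if j != i and np.isfinite(d[i, j])
        ) / (n - 1)
    return out


def _all_shortest_paths(a, d, s, t):
    """Every shortest s->t path, by recursion on predecessors of t."""
    if s == t:
        return [[s]]
    paths = []
    for w in range(len(a)):
        if a[t, w] and d[s, w] == d[s, t] - 1:
            for p in _all_shortest_paths(a, d, s, w):
                paths.append(p + [t])
    return paths


def betweenness(a: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness by explicit shortest-path enumeration."""
    n = len(a)
    d = fw_distances(a)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]) or d[s, t] == 0:
                continue
            paths = _all_shortest_paths(a, d, s, t)
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc
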