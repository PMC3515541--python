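"""Brute-force reference implementations, independent of the package's fast paths.

Used only by the test suite: exhaustive triangle counting for clustering,
Floyd–Warshall for path lengths, exhaustive shortest-path enumeration for
betweenness, and a literal step-up scan for Benjamini–Hochberg.
"""

from itertools import combinations

import numpy as np


def clustering_bruteforce(adj: np.ndarray) -> np.ndarray:
    """Per-node clustering by explicit neighbor-pair loops."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if adj[a, b])
        out[i] = links / (k * (k - 1) / 2)
    return out


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest hop counts by the classic triple loop."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def path_length_bruteforce(adj: np.ndarray) -> float:
    d = floyd_warshall(adj)
    iu = np.triu_indices(adj.shape[0], k=1)
    vals = d[iu]
    return float(vals[np.isfinite(vals)].mean())


def _count_shortest_paths(adj: np.ndarray, s: int, t: int, d: np.ndarray,
                          through=None) -> int:
    """Number of shortest s-t paths (optionally passing through a node),
    by recursive enumeration along the BFS distance gradient."""
    if not np.isfinite(d[s, t]):
        return 0

    def walk(u, visited_through):
        if u == t:
            return 1 if (through is None or visited_through) else 0
        total = 0
        for v in range(adj.shape[0]):
            if adj[u, v] and d[s, v] == d[s, u] + 1 and d[v, t] == d[u, t] - 1:
                total += walk(v, visited_through or v == through)
        return total

    return walk(s, through == s)


def betweenness_bruteforce(adj: np.ndarray) -> np.ndarray:
    """B_i = sum over pairs {s, t} (s,t != i) of sigma_st(i) / sigma_st."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    out = np.zeros(n)
    for i in range(n):
        for s, t in combinations([x for x in range(n) if x != i], 2):
            sigma = _count_shortest_paths(adj, s, t, d)
            if sigma == 0:
                continue
            sigma_i = _count_shortest_paths(adj, s, t, d, through=i)
            out[i] += sigma_i / sigma
    return out


def bh_bruteforce(p_values, q: float) -> np.ndarray:
    """Literal BH definition: largest k with p_(k) <= q k / m."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= q * k / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject
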