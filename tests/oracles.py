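"""Independent brute-force graph oracles for cross-checking the library.

Deliberately naive: hand-rolled BFS over adjacency lists for distances and
direct evaluation of the efficiency definitions by subgraph enumeration.
No scipy/networkx shortest-path machinery is used here.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_distances(a: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest paths by queue-based BFS."""
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    for s in range(n):
        d[s, s] = 0
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in range(n):
                if a[u, v] and np.isinf(d[s, v]):
                    d[s, v] = d[s, u] + 1
                    queue.append(v)
    return d


def brute_degree(a: np.ndarray) -> np.ndarray:
    return np.array([sum(a[i]) for i in range(a.shape[0])], dtype=float)


def brute_nodal_efficiency(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = bfs_distances(a)
    e = np.zeros(n)
    for i in range(n):
        total = 0.0
        for j in range(n):
            if j != i and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
        e[i] = total / (n - 1) if n > 1 else 0.0
    return e


def brute_global_efficiency(a: np.ndarray) -> float:
    n = a.shape[0]
    if n < 2:
        return 0.0
    return float(brute_nodal_efficiency(a).mean())


def brute_local_efficiency(a: np.ndarray) -> float:
    n = a.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        total += brute_global_efficiency(sub)
    return total / n


def all_graphs(n: int):
    """Every labelled undirected graph on n nodes (2^(n(n-1)/2) of them)."""
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for mask in range(2 ** len(pairs)):
        a = np.zeros((n, n), dtype=np.int8)
        for bit, (i, j) in enumerate(pairs):
            if mask >> bit & 1:
                a[i, j] = a[j, i] = 1
        yield a


def random_graph(n: int, rng) -> np.ndarray:
    a = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < rng.uniform(0.1, 0.9):
                a[i, j] = a[j, i] = 1
    return a


def brute_bh(p: np.ndarray, alpha: float) -> np.ndarray:
    """Step-up BH by literal evaluation of the definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank / m * alpha:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    for idx in order[:k_star]:
        reject[idx] = True
    return reject
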