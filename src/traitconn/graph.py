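"""Binary graph model, wiring cost and efficiency-based topology.

The functional connectome is analysed as an undirected graph whose nodes are
brain regions.  All metrics here operate on *binary* (thresholded) graphs:
node degree, nodal efficiency (mean inverse shortest-path length), global
efficiency (mean nodal efficiency) and local efficiency (mean global
efficiency of each node's neighbour-induced subgraph).  Efficiencies are
normalised to [0, 1]; unreachable node pairs contribute zero (the standard
Latora–Marchiori 1/inf = 0 convention), which keeps every metric defined on
the disconnected graphs that low-cost thresholding produces.

Reference networks for small-world validation (uniform random graphs and
ring lattices at a matched wiring cost) live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

__all__ = [
    "BinaryNetwork",
    "max_edges",
    "edge_count_for_cost",
    "wiring_cost",
    "degree",
    "shortest_paths",
    "nodal_efficiency",
    "global_efficiency",
    "local_efficiency",
    "random_network",
    "regular_network",
]


@dataclass
class BinaryNetwork:
    """Undirected unweighted graph as a zero-diagonal symmetric 0/1 matrix."""

    a: np.ndarray
    region_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        a = np.asarray(self.a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency matrix must have a zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.a = a.astype(np.int8)
        if self.region_names is not None and len(self.region_names) != a.shape[0]:
            raise ValueError("region_names length must match node count")

    @property
    def n_nodes(self) -> int:
        return self.a.shape[0]

    @property
    def m_edges(self) -> int:
        """Number of undirected edges (upper-triangle sum)."""
        return int(np.triu(self.a, k=1).sum())


def max_edges(n: int) -> int:
    """Maximum edge count M_C = N(N-1)/2 of an undirected graph on n nodes."""
    if n < 1:
        raise ValueError("node count must be positive")
    return n * (n - 1) // 2


def edge_count_for_cost(cost: float, n: int) -> int:
    """Edge count realising a target wiring cost: round(cost * M_C).

    Uses round-half-to-even, so the achieved cost differs from the target by
    at most 1/(2 M_C).
    """
    if not 0.0 <= cost <= 1.0:
        raise ValueError(f"cost must lie in [0, 1], got {cost}")
    return round(cost * max_edges(n))


def _as_matrix(net) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.a
    if hasattr(net, "w"):  # WeightedNetwork duck type
        return np.asarray(net.w)
    return np.asarray(net)


def wiring_cost(net) -> float:
    """Edge density: mean of the off-diagonal adjacency (or weight) entries.

    For a binary graph this equals M / M_C; for a weighted graph with weights
    in [0, 1] it is the mean off-diagonal weight.
    """
    m = _as_matrix(net)
    n = m.shape[0]
    if n < 2:
        raise ValueError("wiring cost needs at least 2 nodes")
    off = m.sum() - np.trace(m)
    return float(off / (n * (n - 1)))


def degree(net: BinaryNetwork) -> np.ndarray:
    """Node degrees k_i: row sums of the adjacency matrix."""
    return np.asarray(net.a.sum(axis=1), dtype=float)


def shortest_paths(net: BinaryNetwork) -> np.ndarray:
    """Unweighted shortest path length matrix; inf for unreachable pairs."""
    return _bfs_dists(net.a)


def _bfs_dists(a: np.ndarray) -> np.ndarray:
    if a.shape[0] == 0:
        return np.zeros((0, 0))
    if not a.any():
        d = np.full(a.shape, np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    d = _csgraph_shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)
    return d


def _nodal_efficiency_from_dists(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    if n < 2:
        return np.zeros(n)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def nodal_efficiency(net: BinaryNetwork) -> np.ndarray:
    """e_i: average inverse shortest-path length from node i to every other."""
    return _nodal_efficiency_from_dists(_bfs_dists(net.a))


def global_efficiency(net: BinaryNetwork) -> float:
    """E_g: mean of nodal efficiencies."""
    return _global_efficiency_matrix(net.a)


def _global_efficiency_matrix(a: np.ndarray) -> float:
    n = a.shape[0]
    if n < 2:
        return 0.0
    return float(_nodal_efficiency_from_dists(_bfs_dists(a)).mean())


def local_efficiency(net: BinaryNetwork) -> float:
    """E_l: mean over nodes of the neighbour-subgraph global efficiency.

    The subgraph G_i is induced by the neighbours of node i and excludes
    node i itself; nodes with fewer than two neighbours contribute 0.
    """
    return _local_efficiency_matrix(net.a)


def _local_efficiency_matrix(a: np.ndarray) -> float:
    n = a.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        total += _global_efficiency_matrix(sub)
    return total / n


def _network_from_edge_ranks(n: int, edge_idx: np.ndarray) -> BinaryNetwork:
    """Build a BinaryNetwork from flat upper-triangle edge indices."""
    iu, ju = np.triu_indices(n, k=1)
    a = np.zeros((n, n), dtype=np.int8)
    a[iu[edge_idx], ju[edge_idx]] = 1
    a |= a.T
    return BinaryNetwork(a)


def random_network(n: int, cost: float, seed=None) -> BinaryNetwork:
    """Uniform random graph with exactly round(cost * M_C) edges."""
    m = edge_count_for_cost(cost, n)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(max_edges(n), size=m, replace=False)
    return _network_from_edge_ranks(n, chosen)


def regular_network(n: int, cost: float) -> BinaryNetwork:
    """Ring lattice with round(cost * M_C) regularly distributed edges.

    Nearest-neighbour rings are filled outward (offset 1, 2, ...); the
    residual edge budget is assigned deterministically at the next ring,
    starting from node 0.
    """
    m = edge_count_for_cost(cost, n)
    a = np.zeros((n, n), dtype=np.int8)
    placed = 0
    offset = 1
    idx = np.arange(n)
    while placed < m and offset <= n // 2:
        # a full ring at this offset (offset n/2 on even n gives n/2 edges)
        ring_edges = n if (2 * offset < n) else n // 2
        take = min(ring_edges, m - placed)
        src = idx[:take] if take < ring_edges else idx
        dst = (src + offset) % n
        a[src, dst] = 1
        a[dst, src] = 1
        placed += take
        offset += 1
    return BinaryNetwork(a)
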