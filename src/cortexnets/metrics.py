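"""Global small-world metrics and nodal betweenness centrality.

Global topology of a binary network is summarized by the mean clustering
coefficient C, the characteristic path length L (mean shortest-path hop
count over node pairs), and their ratios to degree-matched random nulls:

    gamma = C / C_rand,   lambda = L / L_rand.

A small-world network satisfies gamma >> 1 with lambda ~ 1: locally
clustered like a lattice, globally short like a random graph.

Clustering and path length are computed with vectorized numpy/scipy (the
permutation machinery evaluates tens of thousands of 90-node networks);
betweenness uses the Brandes algorithm via networkx. Brute-force oracles in
the test suite check all three against exhaustive computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ._rng import rng_from
from .networks import BinaryNetwork


@dataclass(frozen=True)
class GlobalMetrics:
    """C, L and their random-null normalizations for one network."""

    clustering_mean: float
    path_length: float
    clustering_random: float | None = None
    path_length_random: float | None = None
    gamma: float | None = None
    lam: float | None = None
    n_random_graphs: int = 0
    disconnected: bool = False

    def as_dict(self) -> dict:
        return {
            "C": self.clustering_mean,
            "L": self.path_length,
            "C_rand": self.clustering_random,
            "L_rand": self.path_length_random,
            "gamma": self.gamma,
            "lambda": self.lam,
            "n_random_graphs": self.n_random_graphs,
            "disconnected": self.disconnected,
        }


@dataclass(frozen=True)
class NodalCentrality:
    """Per-region betweenness centrality (unnormalized shortest-path counts)."""

    betweenness: np.ndarray
    labels: tuple[str, ...] | None = None
    normalized: bool = False


# ---------------------------------------------------------------------------
# clustering


def clustering_per_node(network: BinaryNetwork) -> np.ndarray:
    """Clustering coefficient of every node.

    C_i = (edges among neighbors of i) / (k_i (k_i - 1) / 2); nodes of
    degree < 2 get 0 (the ratio is undefined there; zero keeps C in [0, 1]
    and is the dominant convention).
    """
    a = network.adjacency.astype(np.float64)
    k = a.sum(axis=1)
    # diag(A^3)/2 = triangles through each node
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    possible = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(possible > 0, triangles / possible, 0.0)
    return c


def node_clustering(network: BinaryNetwork, node: int) -> float:
    """Clustering coefficient of a single node."""
    if not 0 <= node < network.n_nodes:
        raise ValueError(f"node {node} not in network of size {network.n_nodes}")
    return float(clustering_per_node(network)[node])


def mean_clustering(network: BinaryNetwork) -> float:
    """Network mean clustering coefficient C (average over all nodes)."""
    if network.n_nodes < 1:
        raise ValueError("empty network")
    return float(clustering_per_node(network).mean())


# ---------------------------------------------------------------------------
# path length


def characteristic_path_length(network: BinaryNetwork) -> tuple[float, bool]:
    """Mean shortest-path length L over node pairs, with a disconnection flag.

    For a disconnected network the mean is taken over connected pairs only
    and the flag is True — infinities are never silently averaged. Callers
    that require connectedness (the pipeline does, at the analysis sparsity)
    must check the flag.
    """
    n = network.n_nodes
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    d = shortest_path(csr_matrix(network.adjacency), method="D", directed=False,
                      unweighted=True)
    iu = np.triu_indices(n, k=1)
    dists = d[iu]
    finite = np.isfinite(dists)
    disconnected = not finite.all()
    if not finite.any():
        raise ValueError("network has no edges; path length undefined")
    return float(dists[finite].mean()), disconnected


# ---------------------------------------------------------------------------
# random-graph nulls


def _rewire_preserving_degrees(
    g: nx.Graph, rng: np.random.Generator, n_swap_factor: int = 10,
    max_retries: int = 10,
) -> nx.Graph:
    """Degree-preserving (Maslov–Sneppen) rewiring, resampled until connected.

    Runs 10·K double-edge swaps. Graphs where no swap is possible (e.g. the
    complete graph) are returned unchanged. If the rewired graph is
    disconnected it is resampled from the original up to ``max_retries``
    times.
    """
    k = g.number_of_edges()
    if k < 2:
        return g.copy()
    for _ in range(max_retries):
        h = g.copy()
        seed = int(rng.integers(0, 2**31 - 1))
        try:
            nx.double_edge_swap(h, nswap=n_swap_factor * k,
                                max_tries=100 * n_swap_factor * k, seed=seed)
        except nx.NetworkXError:
            # no swappable edge pair exists (complete or near-complete graph)
            return g.copy()
        except nx.NetworkXAlgorithmError:
            pass  # max_tries hit: keep however many swaps succeeded
        if not nx.is_connected(g) or nx.is_connected(h):
            return h
    raise RuntimeError(
        f"could not produce a connected degree-preserving null in "
        f"{max_retries} attempts (N={g.number_of_nodes()}, K={k})"
    )


def random_null_metrics(
    network: BinaryNetwork,
    n_null: int = 100,
    seed=None,
    null_model: str = "rewire",
) -> tuple[float, float]:
    """Mean C and L over random null graphs matched to the network.

    ``null_model="rewire"`` (default): degree-preserving rewired graphs —
    same N, same K, same degree sequence. ``"erdos_renyi"``: G(N, K) with
    only N and K matched. Nulls are resampled when disconnected so L_rand
    is always a connected-graph value.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = rng_from(seed)
    n = network.n_nodes
    k = network.edge_count
    c_vals = np.empty(n_null)
    l_vals = np.empty(n_null)
    g = network.to_networkx() if null_model == "rewire" else None
    for i in range(n_null):
        if null_model == "rewire":
            h = _rewire_preserving_degrees(g, rng)
            adj = nx.to_numpy_array(h, dtype=bool, nodelist=range(n))
        elif null_model == "erdos_renyi":
            adj = _connected_gnm(n, k, rng)
        else:
            raise ValueError(f"unknown null model {null_model!r}")
        null_net = BinaryNetwork(adjacency=adj, sparsity=network.sparsity)
        c_vals[i] = mean_clustering(null_net)
        l_vals[i], _ = characteristic_path_length(null_net)
    return float(c_vals.mean()), float(l_vals.mean())


def _connected_gnm(n: int, k: int, rng: np.random.Generator,
                   max_retries: int = 50) -> np.ndarray:
    for _ in range(max_retries):
        g = nx.gnm_random_graph(n, k, seed=int(rng.integers(0, 2**31 - 1)))
        if nx.is_connected(g):
            return nx.to_numpy_array(g, dtype=bool, nodelist=range(n))
    raise RuntimeError(f"no connected G({n},{k}) sample in {max_retries} tries")


def small_world_metrics(
    network: BinaryNetwork,
    n_null: int = 100,
    seed=None,
    null_model: str = "rewire",
) -> GlobalMetrics:
    """Bundle C, L, their null means, and gamma = C/C_rand, lambda = L/L_rand."""
    c = mean_clustering(network)
    l, disconnected = characteristic_path_length(network)
    c_rand, l_rand = random_null_metrics(network, n_null=n_null, seed=seed,
                                         null_model=null_model)
    return GlobalMetrics(
        clustering_mean=c,
        path_length=l,
        clustering_random=c_rand,
        path_length_random=l_rand,
        gamma=c / c_rand if c_rand > 0 else np.inf,
        lam=l / l_rand if l_rand > 0 else np.inf,
        n_random_graphs=n_null,
        disconnected=disconnected,
    )


# ---------------------------------------------------------------------------
# betweenness


def betweenness_all(network: BinaryNetwork, normalized: bool = False) -> NodalCentrality:
    """Betweenness centrality of every region.

    B_i = sum over pairs {j, k} (j != k != i) of the fraction of j–k
    shortest paths passing through i; each unordered pair counted once.
    Unnormalized by default (raw path counts, the scale on which nodal
    group differences are reported); normalization divides by
    (N-1)(N-2)/2.
    """
    g = network.to_networkx()
    bc = nx.betweenness_centrality(g, normalized=normalized)
    values = np.array([bc[i] for i in range(network.n_nodes)])
    return NodalCentrality(betweenness=values, labels=network.labels,
                           normalized=normalized)
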