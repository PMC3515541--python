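import networkx as nx
import numpy as np
import pytest

from cortexnets.networks import BinaryNetwork


def net_from_graph(g: nx.Graph, sparsity: float = 1.0) -> BinaryNetwork:
    """BinaryNetwork from a networkx graph (nodes relabeled 0..N-1)."""
    g = nx.convert_node_labels_to_integers(g, ordering="sorted")
    adj = nx.to_numpy_array(g, dtype=bool, nodelist=range(g.number_of_nodes()))
    return BinaryNetwork(adjacency=adj, sparsity=sparsity)


def net_from_edges(n: int, edges) -> BinaryNetwork:
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return BinaryNetwork(adjacency=adj, sparsity=1.0)


@pytest.fixture(scope="session")
def small_connected_atlas():
    """Every connected graph on 2..6 nodes (exhaustive oracle domain)."""
    graphs = []
    for g in nx.graph_atlas_g():
        n = g.number_of_nodes()
        if 2 <= n <= 6 and nx.is_connected(g):
            graphs.append(net_from_graph(g))
    assert len(graphs) > 100
    return graphs


@pytest.fixture(scope="session")
def tiny_cohort_spec():
    from cortexnets.synthetic import CohortSpec

    return CohortSpec(n_per_group=8, n_regions=40, n_timepoints=80, seed=7)
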