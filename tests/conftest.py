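import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import netripley as nr

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def path5():
    """Path graph a-b-c-d-e."""
    return nr.Network.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])


@pytest.fixture
def triangle():
    return nr.Network.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_connected_network(n, p, rng, weighted=False):
    """Erdos-Renyi style random graph, rejected until connected."""
    import networkx as nx

    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if n > 0 and nx.is_connected(g):
            break
    names = [f"n{i:03d}" for i in range(n)]
    edges = [(names[u], names[v]) for u, v in g.edges]
    scores = None
    dists = None
    if weighted:
        scores = {e: float(rng.uniform(-2, 2)) for e in edges}
        dists = {e: float(rng.uniform(0.05, 1.0)) for e in edges}
    return nr.Network.from_edges(edges, nodes=names, scores=scores, distances=dists)


def binary_weights(net, members):
    w = np.zeros(net.n_nodes)
    for m in members:
        w[net.index_of(m)] = 1.0
    return nr.NodeWeights(w, kind="binary")
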