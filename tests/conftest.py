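import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def triangle():
    return nx.complete_graph(3)


@pytest.fixture
def barbell():
    """Two K5 cliques joined by a single bridge edge (4, 5)."""
    return nx.barbell_graph(5, 0)


@pytest.fixture
def karate():
    from orclust.datasets import karate_club

    return karate_club()


def random_connected_graph(rng, max_n=12, p=0.4):
    """Small connected unweighted graph without isolated vertices."""
    while True:
        n = int(rng.integers(4, max_n + 1))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            return g


@pytest.fixture
def random_tree_deg3():
    """Random trees whose internal vertices all have degree >= 3."""

    def make(rng, n_internal=8):
        g = nx.Graph()
        g.add_node(0)
        internal = [0]
        nxt = 1
        for _ in range(n_internal - 1):
            parent = int(rng.choice(internal))
            g.add_edge(parent, nxt)
            internal.append(nxt)
            nxt += 1
        # pad every internal vertex with leaves up to degree 3
        for v in list(internal):
            while g.degree(v) < 3:
                g.add_edge(v, nxt)
                nxt += 1
        return g

    return make
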