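import networkx as nx
import numpy as np
import pytest

from sescreen import Interactome


@pytest.fixture
def path_graph():
    """a-b-c-d-e path."""
    return Interactome.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])


@pytest.fixture
def small_random_interactome():
    g = nx.gnp_random_graph(60, 0.1, seed=7)
    return Interactome(nx.relabel_nodes(g, {n: f"g{n}" for n in g.nodes}))


def random_interactome(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    return Interactome(nx.relabel_nodes(g, {n: f"g{n}" for n in g.nodes}))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
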