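import networkx as nx
import numpy as np
import pytest

from interbench.network_io import GeneSet, Interactome
from interbench.synthetic_data import SyntheticSpec, gen_network


def make_net(name, edges, confidences=None):
    net = Interactome(name)
    for i, (u, v) in enumerate(edges):
        conf = confidences[i] if confidences else None
        net.add_edge(u, v, conf)
    return net


@pytest.fixture
def two_gene():
    """Single edge A-B: the worked diffusion example."""
    return make_net("two_gene", [("A", "B")])


@pytest.fixture
def triangle():
    return make_net("triangle", [("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star4():
    """Star with center c and three leaves."""
    return make_net("star4", [("c", "x"), ("c", "y"), ("c", "z")])


@pytest.fixture
def path5():
    return make_net("path5", [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])


@pytest.fixture(scope="session")
def ba_small():
    """1000-gene BA network shared by moderate-cost tests."""
    return gen_network(SyntheticSpec(n_genes=1000, n_edges=3000, model="ba",
                                     rng_seed=11, name="ba_small"))


@pytest.fixture(scope="session")
def ba_2000():
    """2000-gene BA network for prioritization-scale tests."""
    return gen_network(SyntheticSpec(n_genes=2000, n_edges=6000, model="ba",
                                     rng_seed=17, name="ba_2000"))


def random_connected_net(rng, n_min=10, n_max=60, name="rand"):
    """Small random connected graph (ER + largest component)."""
    n = int(rng.integers(n_min, n_max))
    m = int(rng.integers(n, 3 * n))
    g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31 - 1)))
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp).copy()
    g = nx.relabel_nodes(g, {v: f"g{v:03d}" for v in g.nodes})
    return Interactome(name, g)
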