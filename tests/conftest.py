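import networkx as nx
import pytest

from netpharm.fixtures import FixtureSpec, fixture_network
from netpharm.network_io import EdgeRecord, WeightedNetwork


def network_from_edges(*triples):
    """Small WeightedNetwork straight from (a, b, weight) triples."""
    g = nx.Graph()
    for a, b, w in triples:
        g.add_edge(a, b, weight=w)
    return WeightedNetwork(graph=g)


def path_network(n, weight=1.0):
    """Path graph N0-N1-...-N(n-1) with uniform edge weights."""
    return network_from_edges(*[(f"N{i}", f"N{i+1}", weight) for i in range(n - 1)])


@pytest.fixture
def two_node_net():
    return network_from_edges(("A", "B", 1.0))


@pytest.fixture
def triangle_net():
    # (A,B) strongest, per the hand-normalization example
    return network_from_edges(("A", "B", 1.0), ("B", "C", 0.5), ("A", "C", 0.5))


@pytest.fixture(scope="session")
def planted_fixture():
    """One 500-node scale-free network with a 30-gene planted disease module."""
    return fixture_network(FixtureSpec(rng_seed=42))
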