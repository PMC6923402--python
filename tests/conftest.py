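import itertools

import networkx as nx
import pytest

from topcontrol.model import EdgeType, RegulatoryEdge, RegulatoryNetwork
from topcontrol.synthetic import generate_toy_network


def net_from_pairs(pairs, edge_type=EdgeType.TF_GENE):
    """Build a network from bare (source, target) pairs, all one edge type."""
    return RegulatoryNetwork(RegulatoryEdge(s, t, edge_type) for s, t in pairs)


def brute_force_mds_size(g: nx.DiGraph) -> int:
    """Smallest dominating set size by exhaustive subset search (directed
    domination: a node covers itself and its out-neighbors)."""
    nodes = list(g.nodes)
    cover = {n: {n} | set(g.successors(n)) for n in nodes}
    for size in range(0, len(nodes) + 1):
        for subset in itertools.combinations(nodes, size):
            covered = set().union(*(cover[n] for n in subset)) if subset else set()
            if covered >= set(nodes):
                return size
    raise AssertionError("unreachable")


def brute_force_min_cds_size(g: nx.DiGraph) -> int:
    """Smallest connected dominating set size of a weakly connected digraph
    (domination directed; connectivity on the underlying undirected graph)."""
    nodes = list(g.nodes)
    und = g.to_undirected()
    cover = {n: {n} | set(g.successors(n)) for n in nodes}
    for size in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, size):
            covered = set().union(*(cover[n] for n in subset))
            if covered >= set(nodes) and nx.is_connected(und.subgraph(subset)):
                return size
    raise AssertionError("no connected dominating set found")


@pytest.fixture(scope="session")
def toy_network():
    return generate_toy_network()


@pytest.fixture()
def triangle_network():
    return net_from_pairs([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture()
def path4_network():
    return net_from_pairs([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture()
def star_network():
    return net_from_pairs([("A", "B"), ("A", "C"), ("A", "D")])
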