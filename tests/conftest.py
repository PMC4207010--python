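import itertools

import networkx as nx
import pytest

from procmod import graphio


@pytest.fixture
def k4_bridge_k4():
    """Two 4-cliques joined by a single bridge edge a3-b0."""
    g = graphio.new_network(name="k4bridge")
    a = [f"a{i}" for i in range(4)]
    b = [f"b{i}" for i in range(4)]
    for clique in (a, b):
        for u, v in itertools.combinations(clique, 2):
            g.add_edge(u, v)
    g.add_edge("a3", "b0")
    return g


@pytest.fixture
def three_cliques():
    """Three disjoint 8-cliques with module labels."""
    g = graphio.new_network(name="cliques")
    labels = {}
    for m in range(3):
        nodes = [f"m{m}_{i}" for i in range(8)]
        for u, v in itertools.combinations(nodes, 2):
            g.add_edge(u, v)
        for n in nodes:
            labels[n] = m
    return g, labels


def clique_graph(*sizes, prefix="c"):
    g = graphio.new_network()
    for ci, size in enumerate(sizes):
        nodes = [f"{prefix}{ci}_{i}" for i in range(size)]
        for u, v in itertools.combinations(nodes, 2):
            g.add_edge(u, v)
    return g


@pytest.fixture
def edge_file(tmp_path):
    def write(rows, name="edges.tsv"):
        path = tmp_path / name
        path.write_text("".join(r + "\n" for r in rows))
        return path

    return write
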