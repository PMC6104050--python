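import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from hetna.netmodel import ColoredNetwork


def random_colored_network(n, p, k, seed, edge_colors=0):
    """Random G(n, p) network with balanced colors, guaranteed non-empty."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    if g.number_of_edges() == 0:
        g.add_edge(0, 1)
    names = [f"v{i:02d}" for i in range(n)]
    edges = [(names[u], names[v]) for u, v in g.edges()]
    order = list(range(n))
    rng.shuffle(order)
    node_color = {names[u]: f"c{(i % k) + 1}" for i, u in enumerate(order)}
    ec = None
    if edge_colors:
        ec = {e: f"e{int(rng.integers(edge_colors)) + 1}" for e in edges}
    return ColoredNetwork(edges, node_color=node_color, edge_color=ec,
                          nodes=names)


@pytest.fixture
def fig3_instance():
    """The 4-node worked example: networks, primed-identity mapping, colors."""
    G = ColoredNetwork(
        [("a", "b"), ("a", "c"), ("a", "d"), ("b", "d"), ("c", "d")],
        node_color={"a": "red", "b": "red", "c": "green", "d": "green"})
    H = ColoredNetwork(
        [("a'", "b'"), ("a'", "c'"), ("b'", "d'"), ("c'", "d'"), ("b'", "c'")],
        node_color={"a'": "red", "b'": "red", "c'": "blue", "d'": "blue"})
    f = {u: u + "'" for u in "abcd"}
    return G, H, f


@pytest.fixture
def triangle():
    return ColoredNetwork([("a", "b"), ("b", "c"), ("a", "c")])
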