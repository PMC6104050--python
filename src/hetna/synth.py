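"""Synthetic evaluation inputs: random networks, colorings, and noise.

Two topology families are provided — geometric random graphs (points in
the unit 3-cube joined by shortest pairwise distances) and scale-free
networks (preferential attachment trimmed/padded to an exact edge
count) — along with balanced random node colorings, membership-list
colorings, and the x%-rewiring noise model that removes a fraction of
edges and replaces them with uniformly chosen non-edges of the original
network, keeping node and edge counts (and all colors) intact and
returning the identity true mapping.
"""

from __future__ import annotations

from typing import List, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist

from .netmodel import ColoredNetwork, TrueMapping

__all__ = [
    "generate_geo",
    "generate_sf",
    "assign_colors_random",
    "assign_colors_membership",
    "rewire_noise",
]


def _node_name(i: int, n: int) -> str:
    return f"v{i:0{len(str(n - 1))}d}"


def _check_sizes(n: int, m: int) -> None:
    if n < 2:
        raise ValueError(f"need at least 2 nodes, got {n}")
    if not (0 < m <= n * (n - 1) // 2):
        raise ValueError(f"infeasible edge count m={m} for n={n}")


def generate_geo(n: int, m: int, seed: int) -> ColoredNetwork:
    """Geometric random graph: n uniform points in the unit 3-cube, m closest pairs."""
    _check_sizes(n, m)
    rng = np.random.default_rng(seed)
    pts = rng.random((n, 3))
    d = pdist(pts)
    # stable sort => distance ties broken by pair index, deterministically
    order = np.argsort(d, kind="stable")[:m]
    iu, ju = np.triu_indices(n, 1)
    edges = [(_node_name(int(iu[o]), n), _node_name(int(ju[o]), n)) for o in order]
    return ColoredNetwork(edges, nodes=[_node_name(i, n) for i in range(n)])


def generate_sf(n: int, m: int, seed: int) -> ColoredNetwork:
    """Scale-free network: preferential attachment, adjusted to exactly m edges."""
    _check_sizes(n, m)
    rng = np.random.default_rng(seed)
    m_att = min(max(1, round(m / n)), n - 1)
    g = nx.barabasi_albert_graph(n, m_att, seed=int(rng.integers(2**31 - 1)))
    edges: Set[Tuple[int, int]] = {(u, v) if u < v else (v, u) for u, v in g.edges()}
    if len(edges) > m:
        drop = rng.choice(len(edges), size=len(edges) - m, replace=False)
        ordered = sorted(edges)
        edges = {e for i, e in enumerate(ordered) if i not in set(drop.tolist())}
    while len(edges) < m:
        u = int(rng.integers(n))
        v = int(rng.integers(n))
        if u == v:
            continue
        e = (u, v) if u < v else (v, u)
        edges.add(e)
    named = [(_node_name(u, n), _node_name(v, n)) for u, v in sorted(edges)]
    return ColoredNetwork(named, nodes=[_node_name(i, n) for i in range(n)])


def assign_colors_random(net: ColoredNetwork, k: int, seed: int) -> ColoredNetwork:
    """Balanced random coloring: class sizes differ by at most one."""
    if not (1 <= k <= net.n_nodes):
        raise ValueError(f"k must be in 1..{net.n_nodes}, got {k}")
    rng = np.random.default_rng(seed)
    order = list(net.nodes)
    rng.shuffle(order)
    colors = {nd: f"c{(i % k) + 1}" for i, nd in enumerate(order)}
    return net.with_node_colors(colors)


def assign_colors_membership(net: ColoredNetwork,
                             lists: Sequence[Tuple[str, Set[str]]],
                             scheme: int) -> ColoredNetwork:
    """Color nodes by membership in up to two annotation lists.

    scheme 2: in list A vs. not.  scheme 3: in A; else in B; else
    neither (A takes precedence).  scheme 4: A only / B only / both /
    neither.
    """
    if scheme not in (2, 3, 4):
        raise ValueError(f"scheme must be 2, 3 or 4, got {scheme}")
    need = 1 if scheme == 2 else 2
    if len(lists) < need:
        raise ValueError(f"scheme {scheme} needs {need} membership lists")
    label_a, set_a = lists[0]
    label_b, set_b = lists[1] if need == 2 else ("", set())

    colors = {}
    for nd in net.nodes:
        in_a, in_b = nd in set_a, nd in set_b
        if scheme == 2:
            colors[nd] = label_a if in_a else f"non-{label_a}"
        elif scheme == 3:
            colors[nd] = label_a if in_a else (label_b if in_b else "neither")
        else:
            if in_a and in_b:
                colors[nd] = "both"
            elif in_a:
                colors[nd] = label_a
            elif in_b:
                colors[nd] = label_b
            else:
                colors[nd] = "neither"
    return net.with_node_colors(colors)


def rewire_noise(net: ColoredNetwork, level: float,
                 seed: int) -> Tuple[ColoredNetwork, TrueMapping]:
    """Rewire a fraction of edges: remove round(level*m) random edges and
    add the same number of uniformly chosen non-edges of the original
    network.  Node set, colors, and edge count are preserved; the true
    node mapping is the identity."""
    if not (0.0 <= level <= 1.0):
        raise ValueError(f"noise level must be in [0, 1], got {level}")
    rng = np.random.default_rng(seed)
    edges = list(net.edges())
    m = len(edges)
    n = net.n_nodes
    n_rewire = int(np.floor(level * m + 0.5))
    truth = TrueMapping({nd: nd for nd in net.nodes})
    if n_rewire == 0:
        return ColoredNetwork(edges, node_color=net.node_color,
                              edge_color=net.edge_color, nodes=net.nodes), truth

    n_nonedges = n * (n - 1) // 2 - m
    if n_nonedges < n_rewire:
        raise ValueError("not enough disconnected pairs to rewire at this level")

    remove_idx = set(rng.choice(m, size=n_rewire, replace=False).tolist())
    kept = [e for i, e in enumerate(edges) if i not in remove_idx]

    nodes = net.nodes
    original = set(edges)
    added: Set[Tuple[str, str]] = set()
    if n_nonedges <= 3 * n_rewire:
        # dense regime: enumerate all original non-edges and sample exactly
        nonedges = [
            (nodes[i], nodes[j])
            for i in range(n) for j in range(i + 1, n)
            if (nodes[i], nodes[j]) not in original
        ]
        pick = rng.choice(len(nonedges), size=n_rewire, replace=False)
        added = {nonedges[int(i)] for i in pick}
    else:
        while len(added) < n_rewire:
            i = int(rng.integers(n))
            j = int(rng.integers(n))
            if i == j:
                continue
            e = (nodes[i], nodes[j]) if nodes[i] < nodes[j] else (nodes[j], nodes[i])
            if e in original or e in added:
                continue
            added.add(e)

    new_edges = kept + sorted(added)
    noisy = ColoredNetwork(new_edges, node_color=net.node_color, nodes=net.nodes)
    return noisy, truth
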