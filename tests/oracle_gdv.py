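"""Independent brute-force graphlet counter used as a test oracle.

Enumerates *all* node subsets of size 2..5 with itertools, keeps the
connected ones (networkx), classifies each induced subgraph against the
catalog by VF2 isomorphism matching, and reads the touched orbit off the
matched position.  Shares nothing with the production path except the
catalog's orbit numbering, which is itself validated separately against
brute-force automorphism computation.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import networkx as nx
from networkx.algorithms.isomorphism import GraphMatcher

from hetna.graphlets import build_catalog


def brute_force_counts(net, max_size=5):
    """Per-node dicts: (orbit, frozenset of node colors) -> count and
    (orbit, frozenset of edge colors) -> count (edge part only when the
    network carries edge colors)."""
    cat = build_catalog(5)
    g = net.to_networkx()
    by_size = defaultdict(list)
    for glet in cat.graphlets:
        by_size[(glet.size, glet.n_edges)].append((glet, glet.to_networkx()))

    counts_n = {u: defaultdict(int) for u in net.nodes}
    counts_e = {u: defaultdict(int) for u in net.nodes}
    for s in range(2, max_size + 1):
        for sub in itertools.combinations(net.nodes, s):
            sg = g.subgraph(sub)
            if not nx.is_connected(sg):
                continue
            ncombo = frozenset(net.node_color[x] for x in sub)
            if net.edge_color is not None:
                ecombo = frozenset(
                    net.edge_color[(x, y) if x <= y else (y, x)]
                    for x, y in sg.edges())
            else:
                ecombo = frozenset()
            for glet, glet_nx in by_size[(s, sg.number_of_edges())]:
                gm = GraphMatcher(sg, glet_nx)
                if gm.is_isomorphic():
                    for x in sub:
                        orb = glet.node_orbit[gm.mapping[x]]
                        counts_n[x][(orb, ncombo)] += 1
                        counts_e[x][(orb, ecombo)] += 1
                    break
            else:  # pragma: no cover
                raise AssertionError("connected subgraph missing from catalog")
    return counts_n, counts_e


def frame_to_dicts(sig, colors, kind="n"):
    """Convert a package signature DataFrame to the oracle's dict keying."""
    k = len(colors)
    ncombo = 2**k - 1
    out = {}
    for node in sig.index:
        row = sig.loc[node]
        d = defaultdict(int)
        for col_idx, v in enumerate(row.to_numpy()):
            if v == 0:
                continue
            orbit, rem = divmod(col_idx, ncombo)
            bits = rem + 1
            combo = frozenset(c for i, c in enumerate(colors) if bits >> i & 1)
            d[(orbit, combo)] += int(v)
        out[node] = d
    return out
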