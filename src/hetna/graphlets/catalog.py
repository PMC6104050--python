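"""Catalog of 2-5-node graphlets with automorphism node orbits.

A graphlet on ``s`` nodes is encoded as a bitmask over the ``s*(s-1)/2``
unordered node pairs, with bit ``j*(j-1)/2 + i`` standing for the pair
``(i, j)``, ``i < j``.  The canonical form of a labeled graph is the
minimum bitmask over all node permutations; automorphisms are the
permutations fixing the canonical mask.  Graphlets are ordered by
(node count, edge count, canonical mask) and their orbits are numbered
globally in that order; at the full size range 2-5 this yields 30
graphlets and 73 orbits.

The module also precomputes, for each size ``s``, a dense lookup table
``orbit_table[s][mask][pos]`` mapping any connected labeled graph and
node position to the global orbit id (-1 for disconnected masks); the
counting kernels classify enumerated induced subgraphs with a single
table lookup.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "Graphlet",
    "GraphletCatalog",
    "build_catalog",
    "enumerate_colored_variants",
    "pair_bit",
]

MIN_SIZE, MAX_SIZE = 2, 5

_PERMS: Dict[int, List[Tuple[int, ...]]] = {
    s: list(itertools.permutations(range(s))) for s in range(MIN_SIZE, MAX_SIZE + 1)
}


def pair_bit(i: int, j: int) -> int:
    """Bit index of unordered node pair (i, j), i < j."""
    if i > j:
        i, j = j, i
    return j * (j - 1) // 2 + i


def mask_edges(mask: int, s: int) -> List[Tuple[int, int]]:
    return [
        (i, j)
        for j in range(s)
        for i in range(j)
        if mask >> pair_bit(i, j) & 1
    ]


def permute_mask(mask: int, perm: Tuple[int, ...], s: int) -> int:
    """Relabel nodes of a mask-encoded graph: node i becomes perm[i]."""
    out = 0
    for j in range(s):
        for i in range(j):
            if mask >> pair_bit(i, j) & 1:
                out |= 1 << pair_bit(perm[i], perm[j])
    return out


def is_connected_mask(mask: int, s: int) -> bool:
    adj = [0] * s
    for i, j in mask_edges(mask, s):
        adj[i] |= 1 << j
        adj[j] |= 1 << i
    seen = 1
    frontier = [0]
    while frontier:
        v = frontier.pop()
        nbrs = adj[v] & ~seen
        while nbrs:
            b = nbrs & -nbrs
            u = b.bit_length() - 1
            seen |= b
            frontier.append(u)
            nbrs ^= b
    return seen == (1 << s) - 1


def canonical_mask(mask: int, s: int) -> int:
    return min(permute_mask(mask, p, s) for p in _PERMS[s])


@dataclass(frozen=True)
class Graphlet:
    """One connected non-isomorphic graph together with its node orbits."""

    index: int                      # position in the catalog (G_0, G_1, ...)
    size: int                       # number of nodes
    canon: int                      # canonical edge bitmask
    orbits: Tuple[Tuple[int, ...], ...]   # node positions partitioned by orbit
    orbit_ids: Tuple[int, ...]      # global orbit id of each orbit class
    node_orbit: Tuple[int, ...]     # per-position global orbit id

    @property
    def n_edges(self) -> int:
        return bin(self.canon).count("1")

    @property
    def edges(self) -> List[Tuple[int, int]]:
        return mask_edges(self.canon, self.size)

    def automorphisms(self) -> List[Tuple[int, ...]]:
        return [p for p in _PERMS[self.size]
                if permute_mask(self.canon, p, self.size) == self.canon]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.size))
        g.add_edges_from(self.edges)
        return g


class GraphletCatalog:
    """Ordered graphlets on MIN_SIZE..max_size nodes with orbit numbering."""

    def __init__(self, max_size: int):
        if not (MIN_SIZE <= max_size <= MAX_SIZE):
            raise ValueError(f"max_size must be in {MIN_SIZE}..{MAX_SIZE}, got {max_size}")
        self.max_size = max_size
        self.graphlets: List[Graphlet] = []
        self._by_canon: Dict[Tuple[int, int], Graphlet] = {}
        self.orbit_table: Dict[int, np.ndarray] = {}

        orbit_counter = 0
        for s in range(MIN_SIZE, max_size + 1):
            nbits = s * (s - 1) // 2
            canon_of = np.full(1 << nbits, -1, dtype=np.int64)
            canon_set = set()
            for mask in range(1, 1 << nbits):
                if not is_connected_mask(mask, s):
                    continue
                c = canonical_mask(mask, s)
                canon_of[mask] = c
                canon_set.add(c)

            table = np.full((1 << nbits, s), -1, dtype=np.int8)
            reps = sorted(canon_set, key=lambda c: (bin(c).count("1"), c))
            canon_to_graphlet = {}
            for c in reps:
                autos = [p for p in _PERMS[s] if permute_mask(c, p, s) == c]
                # orbit of position i = {p[i] : p automorphism}
                classes: List[Tuple[int, ...]] = []
                assigned = [-1] * s
                for i in range(s):
                    if assigned[i] >= 0:
                        continue
                    orb = tuple(sorted({p[i] for p in autos}))
                    cid = len(classes)
                    classes.append(orb)
                    for j in orb:
                        assigned[j] = cid
                orbit_ids = tuple(orbit_counter + c_ for c_ in range(len(classes)))
                node_orbit = tuple(orbit_ids[assigned[i]] for i in range(s))
                g = Graphlet(
                    index=len(self.graphlets),
                    size=s,
                    canon=c,
                    orbits=tuple(classes),
                    orbit_ids=orbit_ids,
                    node_orbit=node_orbit,
                )
                orbit_counter += len(classes)
                self.graphlets.append(g)
                self._by_canon[(s, c)] = g
                canon_to_graphlet[c] = g

            # dense classification table for labeled masks
            for mask in range(1, 1 << nbits):
                c = canon_of[mask]
                if c < 0:
                    continue
                g = canon_to_graphlet[c]
                for p in _PERMS[s]:
                    if permute_mask(mask, p, s) == c:
                        # node at position i of `mask` plays position p[i] in canon
                        for i in range(s):
                            table[mask, i] = g.node_orbit[p[i]]
                        break
            self.orbit_table[s] = table

        self.n_orbits = orbit_counter

    @property
    def n_graphlets(self) -> int:
        return len(self.graphlets)

    def lookup(self, size: int, canon: int) -> Graphlet:
        return self._by_canon[(size, canon)]

    def orbit_labels(self) -> List[str]:
        return [f"o{i}" for i in range(self.n_orbits)]

    def __repr__(self):
        return (f"GraphletCatalog(max_size={self.max_size}, "
                f"graphlets={self.n_graphlets}, orbits={self.n_orbits})")


@lru_cache(maxsize=None)
def build_catalog(max_size: int = MAX_SIZE) -> GraphletCatalog:
    """Catalog of all connected non-isomorphic graphs on 2..max_size nodes."""
    return GraphletCatalog(max_size)


def enumerate_colored_variants(graphlet: Graphlet, k: int, scheme: str = "combination") -> int:
    """Number of colored variants of a graphlet under ``k`` node colors.

    ``scheme="combination"`` tracks only which colors appear, giving
    ``2**k - 1`` variants for every graphlet.  ``scheme="exhaustive"``
    counts position-specific colorings up to graphlet automorphism by
    brute force (the space-hungry alternative the combination scheme
    avoids).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if scheme == "combination":
        return 2**k - 1
    if scheme != "exhaustive":
        raise ValueError(f"unknown scheme {scheme!r}")

    s = graphlet.size
    autos = graphlet.automorphisms()
    seen = set()
    for coloring in itertools.product(range(k), repeat=s):
        # p sends position i to p[i]; the recolored graph assigns
        # coloring[i] to node p[i].
        rep = min(
            tuple(coloring[inv[j]] for j in range(s))
            for inv in (_invert(p) for p in autos)
        )
        seen.add(rep)
    return len(seen)


def _invert(p: Tuple[int, ...]) -> Tuple[int, ...]:
    inv = [0] * len(p)
    for i, j in enumerate(p):
        inv[j] = i
    return tuple(inv)
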