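"""Seed-and-extend alignment guided by node similarity and neighbor votes.

The highest-similarity unaligned cross pair is seeded; afterwards a
frontier of candidate pairs (g, h) — with g adjacent to an aligned
source and h adjacent to its image — is kept in a max-heap scored by
sim(g, h) plus the number of already-aligned neighbor pairs supporting
the candidate.  Ties break lexicographically on (g, h).  If the frontier
drains before every source node is aligned (disconnected leftovers), a
fresh seed is picked among the remaining nodes by best similarity.
Edge conservation is optimized only implicitly through the votes.
"""

from __future__ import annotations

import heapq
from typing import Dict

import numpy as np

from ..netmodel import Alignment, ColoredNetwork, SimilarityMatrix

__all__ = ["wave_align"]


def wave_align(G: ColoredNetwork, H: ColoredNetwork,
               sim: SimilarityMatrix) -> Alignment:
    if G.n_nodes > H.n_nodes:
        raise ValueError("source network is larger than the target; swap the arguments")
    if tuple(sim.nodes_g) != G.nodes or tuple(sim.nodes_h) != H.nodes:
        raise ValueError("similarity matrix does not cover the networks' node sets")

    nodes_g, nodes_h = G.nodes, H.nodes
    values = sim.values
    aligned_g: Dict[str, str] = {}
    aligned_h: Dict[str, str] = {}
    free_g = np.ones(len(nodes_g), dtype=bool)
    free_h = np.ones(len(nodes_h), dtype=bool)
    ig = {u: i for i, u in enumerate(nodes_g)}
    ih = {v: j for j, v in enumerate(nodes_h)}

    votes: Dict[tuple, int] = {}
    heap = []  # (-score, g, h, votes_at_push)

    # one-time descending similarity order for (re-)seeding; stable sort
    # breaks ties in row-major = lexicographic (g, h) order on the
    # sorted node lists
    seed_order = np.argsort(-values, axis=None, kind="stable")
    seed_ptr = 0
    n_h = len(nodes_h)

    def best_seed():
        nonlocal seed_ptr
        while True:
            flat = int(seed_order[seed_ptr])
            seed_ptr += 1
            i, j = divmod(flat, n_h)
            if free_g[i] and free_h[j]:
                return nodes_g[i], nodes_h[j]

    def commit(g, h):
        aligned_g[g] = h
        aligned_h[h] = g
        free_g[ig[g]] = False
        free_h[ih[h]] = False
        for g2 in G.neighbors(g):
            if g2 in aligned_g:
                continue
            row = values[ig[g2]]
            for h2 in H.neighbors(h):
                if h2 in aligned_h:
                    continue
                key = (g2, h2)
                nv = votes.get(key, 0) + 1
                votes[key] = nv
                heapq.heappush(heap, (-(row[ih[h2]] + nv), g2, h2, nv))

    while len(aligned_g) < len(nodes_g):
        if not heap:
            commit(*best_seed())
            continue
        neg, g, h, v = heapq.heappop(heap)
        if g in aligned_g or h in aligned_h:
            continue
        if votes.get((g, h), 0) != v:
            continue  # stale entry; a fresher one is in the heap
        commit(g, h)

    return Alignment(aligned_g, method="wave")
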