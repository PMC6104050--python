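"""Simulated-annealing alignment search with swap / change neighbors.

Starts from a seeded uniformly-random injective mapping and explores
neighboring alignments: a *swap* exchanges the images of two source
nodes, a *change* re-images one source node to an unused target node
(when the networks are the same size only swaps exist).  Improving moves
are always accepted; worsening moves are accepted with probability
exp(delta / T) under a geometric temperature decay calibrated so that
roughly half of the worsening moves are accepted at the start and
essentially none near the end.  The objective alpha*NC + (1-alpha)*EC is
evaluated incrementally.  The final-iteration alignment is returned,
with its objective recomputed from scratch.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Optional

import numpy as np

from ..conservation import SearchState, combined_objective, _as_fractions
from ..netmodel import Alignment, ColoredNetwork, SimilarityMatrix
from . import _sana_kernel
from .objective import ObjectiveConfig

__all__ = ["sana_align"]

_CALIBRATION_SAMPLES = 200


def _calibrate(state: SearchState, n_h: int, rng: np.random.Generator):
    """Initial temperature from the typical size of a worsening move."""
    nodes_g = list(state.f)
    unused = [x for x in state.H.nodes if x not in state.inv]
    neg = []
    for _ in range(_CALIBRATION_SAMPLES):
        if unused and rng.random() < len(unused) / (len(unused) + len(nodes_g)):
            u = nodes_g[rng.integers(len(nodes_g))]
            hn = unused[rng.integers(len(unused))]
            d = state.delta_objective(("change", u, hn))
        else:
            i = rng.integers(len(nodes_g))
            j = rng.integers(len(nodes_g) - 1)
            if j >= i:
                j += 1
            d = state.delta_objective(("swap", nodes_g[i], nodes_g[j]))
        if d < 0:
            neg.append(-d)
    mean_neg = float(np.mean(neg)) if neg else 1e-3
    return max(mean_neg / math.log(2.0), 1e-12)


def sana_align(G: ColoredNetwork, H: ColoredNetwork, sim: SimilarityMatrix,
               objective: Optional[ObjectiveConfig] = None,
               budget: int = 200_000, seed: int = 0,
               engine: str = "auto") -> Alignment:
    """Align G (smaller) into H by simulated annealing.

    ``budget`` is the number of iterations; identical
    (inputs, seed, budget, engine) yield identical alignments.
    """
    if G.n_nodes > H.n_nodes:
        raise ValueError("source network is larger than the target; swap the arguments")
    if not isinstance(budget, int) or budget <= 0:
        raise ValueError(f"budget must be a positive iteration count, got {budget!r}")
    if objective is None:
        objective = ObjectiveConfig()
    if tuple(sim.nodes_g) != G.nodes or tuple(sim.nodes_h) != H.nodes:
        raise ValueError("similarity matrix does not cover the networks' node sets")

    rng = np.random.default_rng(seed)
    n_g, n_h = G.n_nodes, H.n_nodes
    fg0 = rng.permutation(n_h)[:n_g].astype(np.int64)
    mapping0 = {G.nodes[i]: H.nodes[int(fg0[i])] for i in range(n_g)}

    state = SearchState(G, H, sim, mapping0, alpha=objective.alpha,
                        ec_measure=objective.ec_measure, weights=objective.weights)
    t0 = _calibrate(state, n_h, rng)
    t_end = t0 * 1e-9
    lam = (t_end / t0) ** (1.0 / budget)

    use_numba = _sana_kernel.HAVE_NUMBA if engine == "auto" else (engine == "numba")
    if use_numba and not _sana_kernel.HAVE_NUMBA:
        raise RuntimeError("numba engine requested but numba is unavailable")

    if use_numba:
        fg = _run_numba(G, H, sim, objective, fg0, budget, t0, lam,
                        int(rng.integers(2**31 - 1)))
        mapping = {G.nodes[i]: H.nodes[int(fg[i])] for i in range(n_g)}
    else:
        mapping = _run_python(state, budget, t0, lam, rng)

    obj = combined_objective(G, H, mapping, sim, alpha=objective.alpha,
                             ec_measure=objective.ec_measure,
                             weights=objective.weights)
    return Alignment(mapping, method="sana", seed=seed, objective=obj)


def _weight_numerators(objective: ObjectiveConfig):
    if objective.ec_measure == "homs3":
        fracs = (Fraction(1), Fraction(1), Fraction(1))
    else:
        fracs = _as_fractions(objective.weights)
    den = 1
    for f in fracs:
        den = den * f.denominator // math.gcd(den, f.denominator)
    w2, w1, w0 = (int(f * den) for f in fracs)
    # kernel indexes weights by number of color matches (0, 1, 2)
    return np.array([w0, w1, w2], dtype=np.int64), den


def _csr_int(net: ColoredNetwork):
    nodes = net.nodes
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    indptr = np.zeros(n + 1, dtype=np.int64)
    for i, u in enumerate(nodes):
        indptr[i + 1] = indptr[i] + net.degree(u)
    indices = np.empty(indptr[-1], dtype=np.int64)
    for i, u in enumerate(nodes):
        indices[indptr[i]:indptr[i + 1]] = sorted(index[v] for v in net.neighbors(u))
    return indptr, indices


def _color_ids(G: ColoredNetwork, H: ColoredNetwork):
    labels = sorted(set(G.node_color.values()) | set(H.node_color.values()))
    lut = {c: i for i, c in enumerate(labels)}
    cg = np.array([lut[G.node_color[u]] for u in G.nodes], dtype=np.int64)
    ch = np.array([lut[H.node_color[v]] for v in H.nodes], dtype=np.int64)
    return cg, ch


def _run_numba(G, H, sim, objective, fg0, budget, t0, lam, kseed):
    g_indptr, g_indices = _csr_int(G)
    h_indptr, h_indices = _csr_int(H)
    cg, ch = _color_ids(G, H)
    wnum, wden = _weight_numerators(objective)
    fg = fg0.copy()
    _sana_kernel._anneal(g_indptr, g_indices, h_indptr, h_indices,
                         cg, ch, np.ascontiguousarray(sim.values, dtype=np.float64),
                         fg, wnum, wden, float(objective.alpha),
                         int(budget), float(t0), float(lam), kseed)
    return fg


def _run_python(state: SearchState, budget, t0, lam, rng):
    nodes_g = list(state.G.nodes)
    unused = [x for x in state.H.nodes if x not in state.inv]
    n_g = len(nodes_g)
    n_h = state.H.n_nodes
    n_changes = n_g * (n_h - n_g)
    n_swaps = n_g * (n_g - 1) // 2
    p_change = n_changes / (n_changes + n_swaps)
    T = t0
    for _ in range(budget):
        T *= lam
        if rng.random() < p_change:
            u = nodes_g[rng.integers(n_g)]
            j = int(rng.integers(len(unused)))
            move = ("change", u, unused[j])
        else:
            i = int(rng.integers(n_g))
            j2 = int(rng.integers(n_g - 1))
            if j2 >= i:
                j2 += 1
            move = ("swap", nodes_g[i], nodes_g[j2])
            j = -1
        d = state.delta_objective(move)
        if d >= 0 or rng.random() < math.exp(d / T):
            if move[0] == "change":
                unused[j] = state.f[move[1]]
            state.apply(move)
    return dict(state.f)
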