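"""Genetic alignment search: crossover of injective mappings.

A population of random injective mappings evolves for a fixed number of
generations.  Each generation the fitter half survives (elitism) and the
population is refilled with children produced by crossing over two
parents sampled with probability proportional to fitness: a uniform
random mask picks each source node's image from one parent, and
conflicts (duplicate images) are repaired by falling back to the other
parent's image or, failing that, drawing from the remaining unused
targets.  The best alignment ever seen is returned.

The historical defaults (population 15,000, 2,000 generations) suit
overnight runs; tests and desk-scale experiments override them.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ..netmodel import Alignment, ColoredNetwork, SimilarityMatrix
from .objective import ObjectiveConfig

__all__ = ["magna_align"]


class _Evaluator:
    """Vectorized objective evaluation for integer-array mappings."""

    def __init__(self, G: ColoredNetwork, H: ColoredNetwork,
                 sim: SimilarityMatrix, objective: ObjectiveConfig):
        n_g, n_h = G.n_nodes, H.n_nodes
        ig = {u: i for i, u in enumerate(G.nodes)}
        ih = {v: j for j, v in enumerate(H.nodes)}
        ge = np.array([(ig[u], ig[v]) for u, v in G.edges()], dtype=np.int64)
        he = np.array([(ih[u], ih[v]) for u, v in H.edges()], dtype=np.int64)
        self.ge_u, self.ge_v = ge[:, 0], ge[:, 1]
        self.he_u, self.he_v = (he[:, 0], he[:, 1]) if len(he) else \
            (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64))
        self.h_adj = np.zeros((n_h, n_h), dtype=bool)
        self.h_adj[self.he_u, self.he_v] = True
        self.h_adj[self.he_v, self.he_u] = True
        cg = np.array([G.node_color[u] for u in G.nodes])
        ch = np.array([H.node_color[v] for v in H.nodes])
        self.cmatch = cg[:, None] == ch[None, :]
        self.sim = sim.values
        self.m_g = G.n_edges
        self.n_g, self.n_h = n_g, n_h
        self.alpha = objective.alpha
        if objective.ec_measure == "homs3":
            self.w = np.array([1.0, 1.0, 1.0])
        else:
            w2, w1, w0 = objective.weights
            self.w = np.array([float(w0), float(w1), float(w2)])
        self._src = np.arange(n_g)

    def fitness(self, fg: np.ndarray) -> float:
        iu, iv = fg[self.ge_u], fg[self.ge_v]
        cons_mask = self.h_adj[iu, iv]
        matches = (self.cmatch[self.ge_u, iu].astype(np.int64)
                   + self.cmatch[self.ge_v, iv])
        conserved = int(cons_mask.sum())
        total_w = float(self.w[matches[cons_mask]].sum())
        in_img = np.zeros(self.n_h, dtype=bool)
        in_img[fg] = True
        e_ind = int((in_img[self.he_u] & in_img[self.he_v]).sum())
        noncons = (self.m_g - conserved) + (e_ind - conserved)
        denom = total_w + noncons
        ec = total_w / denom if denom > 0 else 0.0
        nc = float(self.sim[self._src, fg].mean())
        return self.alpha * nc + (1.0 - self.alpha) * ec


def _crossover(p1: np.ndarray, p2: np.ndarray, n_h: int,
               rng: np.random.Generator) -> np.ndarray:
    n_g = len(p1)
    mask = rng.random(n_g) < 0.5
    child = np.where(mask, p1, p2)
    used = np.zeros(n_h, dtype=bool)
    conflicts = []
    for i in range(n_g):
        img = child[i]
        if used[img]:
            conflicts.append(i)
        else:
            used[img] = True
    if not conflicts:
        return child
    leftovers = []
    for i in conflicts:
        alt = p2[i] if mask[i] else p1[i]  # the other parent's image
        if not used[alt]:
            child[i] = alt
            used[alt] = True
        else:
            leftovers.append(i)
    if leftovers:
        free = np.flatnonzero(~used)
        pick = rng.permutation(len(free))[:len(leftovers)]
        for i, j in zip(leftovers, pick):
            child[i] = free[j]
            used[free[j]] = True
    return child


def magna_align(G: ColoredNetwork, H: ColoredNetwork, sim: SimilarityMatrix,
                objective: Optional[ObjectiveConfig] = None,
                population: int = 15_000, generations: int = 2_000,
                seed: int = 0) -> Alignment:
    """Align G (smaller) into H by genetic search over injective mappings."""
    if G.n_nodes > H.n_nodes:
        raise ValueError("source network is larger than the target; swap the arguments")
    if population < 2:
        raise ValueError(f"population must be >= 2, got {population}")
    if generations < 1:
        raise ValueError(f"generations must be >= 1, got {generations}")
    if objective is None:
        objective = ObjectiveConfig()
    if tuple(sim.nodes_g) != G.nodes or tuple(sim.nodes_h) != H.nodes:
        raise ValueError("similarity matrix does not cover the networks' node sets")

    rng = np.random.default_rng(seed)
    n_g, n_h = G.n_nodes, H.n_nodes
    ev = _Evaluator(G, H, sim, objective)

    pop = [rng.permutation(n_h)[:n_g].astype(np.int64) for _ in range(population)]
    fit = np.array([ev.fitness(p) for p in pop])
    best_idx = int(np.argmax(fit))
    best, best_fit = pop[best_idx].copy(), float(fit[best_idx])

    n_elite = max(1, population // 2)
    for _ in range(generations):
        order = np.argsort(-fit, kind="stable")
        elite = [pop[i] for i in order[:n_elite]]
        elite_fit = fit[order[:n_elite]]
        # fitness-proportional parent sampling (shifted to be positive)
        probs = elite_fit - elite_fit.min() + 1e-12
        probs = probs / probs.sum()
        children = []
        child_fit = []
        while len(children) < population - n_elite:
            i, j = rng.choice(len(elite), size=2, p=probs)
            child = _crossover(elite[i], elite[j], n_h, rng)
            children.append(child)
            child_fit.append(ev.fitness(child))
        pop = elite + children
        fit = np.concatenate([elite_fit, np.array(child_fit)]) if child_fit \
            else elite_fit
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best, best_fit = pop[gen_best].copy(), float(fit[gen_best])

    mapping = {G.nodes[i]: H.nodes[int(best[i])] for i in range(n_g)}
    return Alignment(mapping, method="magna", seed=seed, objective=best_fit)
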