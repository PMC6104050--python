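"""Numba inner loop for simulated-annealing alignment search.

The kernel maintains exact integer tallies of conserved edges per
endpoint-color-match class (weights are passed as integer numerators
over a common denominator, so the edge-conservation ratio is computed
without drift), the number of target-network edges induced on the image
set, and the aligned-pair similarity sum.  Each iteration proposes a
swap or change move uniformly among legal moves, evaluates the exact
objective delta in O(degree) time, and accepts by the Metropolis rule
under a geometrically decaying temperature.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _has_edge(indptr, indices, u, v):
    lo = indptr[u]
    hi = indptr[u + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        w = indices[mid]
        if w == v:
            return True
        if w < v:
            lo = mid + 1
        else:
            hi = mid
    return False


@njit(cache=True)
def _objective(alpha, wnum, wden, mc, eind, mg, sim_sum, n_g):
    total_num = wnum[0] * mc[0] + wnum[1] * mc[1] + wnum[2] * mc[2]
    conserved = mc[0] + mc[1] + mc[2]
    noncons = (mg - conserved) + (eind - conserved)
    denom = total_num + wden * noncons
    ec = total_num / denom if denom > 0 else 0.0
    return alpha * (sim_sum / n_g) + (1.0 - alpha) * ec


@njit(cache=True)
def _anneal(g_indptr, g_indices, h_indptr, h_indices,
            cg, ch, sim, fg, wnum, wden, alpha,
            n_iter, t0, lam, seed):
    np.random.seed(seed)
    n_g = len(g_indptr) - 1
    n_h = len(h_indptr) - 1
    mg = len(g_indices) // 2

    gh = np.full(n_h, -1, dtype=np.int64)
    for u in range(n_g):
        gh[fg[u]] = u

    unused = np.empty(n_h - n_g, dtype=np.int64)
    upos = np.full(n_h, -1, dtype=np.int64)
    c = 0
    for x in range(n_h):
        if gh[x] < 0:
            unused[c] = x
            upos[x] = c
            c += 1

    mc = np.zeros(3, dtype=np.int64)
    for u in range(n_g):
        for ptr in range(g_indptr[u], g_indptr[u + 1]):
            v = g_indices[ptr]
            if v <= u:
                continue
            if _has_edge(h_indptr, h_indices, fg[u], fg[v]):
                m = 0
                if cg[u] == ch[fg[u]]:
                    m += 1
                if cg[v] == ch[fg[v]]:
                    m += 1
                mc[m] += 1
    eind = 0
    for x in range(n_h):
        if gh[x] < 0:
            continue
        for ptr in range(h_indptr[x], h_indptr[x + 1]):
            y = h_indices[ptr]
            if y > x and gh[y] >= 0:
                eind += 1
    sim_sum = 0.0
    for u in range(n_g):
        sim_sum += sim[u, fg[u]]

    n_changes = n_g * (n_h - n_g)
    n_swaps = n_g * (n_g - 1) // 2
    p_change = n_changes / (n_changes + n_swaps)

    obj = _objective(alpha, wnum, wden, mc, eind, mg, sim_sum, n_g)
    T = t0
    d_mc = np.zeros(3, dtype=np.int64)

    for _ in range(n_iter):
        T *= lam
        if np.random.random() < p_change:
            # ---- change move -------------------------------------------
            u = np.random.randint(0, n_g)
            j = np.random.randint(0, n_h - n_g)
            hn = unused[j]
            old = fg[u]
            d_mc[0] = 0
            d_mc[1] = 0
            d_mc[2] = 0
            for ptr in range(g_indptr[u], g_indptr[u + 1]):
                x = g_indices[ptr]
                fx = fg[x]
                mx = 1 if cg[x] == ch[fx] else 0
                if _has_edge(h_indptr, h_indices, old, fx):
                    m = mx + (1 if cg[u] == ch[old] else 0)
                    d_mc[m] -= 1
                if _has_edge(h_indptr, h_indices, hn, fx):
                    m = mx + (1 if cg[u] == ch[hn] else 0)
                    d_mc[m] += 1
            d_eind = 0
            for ptr in range(h_indptr[old], h_indptr[old + 1]):
                y = h_indices[ptr]
                if gh[y] >= 0:
                    d_eind -= 1
            for ptr in range(h_indptr[hn], h_indptr[hn + 1]):
                y = h_indices[ptr]
                if y != old and gh[y] >= 0:
                    d_eind += 1
            d_sim = sim[u, hn] - sim[u, old]
            new_obj = _objective(alpha, wnum, wden, mc + d_mc, eind + d_eind,
                                 mg, sim_sum + d_sim, n_g)
            d = new_obj - obj
            if d >= 0.0 or np.random.random() < np.exp(d / T):
                mc += d_mc
                eind += d_eind
                sim_sum += d_sim
                obj = new_obj
                fg[u] = hn
                gh[old] = -1
                gh[hn] = u
                unused[j] = old
                upos[old] = j
                upos[hn] = -1
        else:
            # ---- swap move ---------------------------------------------
            u = np.random.randint(0, n_g)
            v = np.random.randint(0, n_g - 1)
            if v >= u:
                v += 1
            fu = fg[u]
            fv = fg[v]
            d_mc[0] = 0
            d_mc[1] = 0
            d_mc[2] = 0
            for a, old_img, new_img, other in ((u, fu, fv, v), (v, fv, fu, u)):
                ma_old = 1 if cg[a] == ch[old_img] else 0
                ma_new = 1 if cg[a] == ch[new_img] else 0
                for ptr in range(g_indptr[a], g_indptr[a + 1]):
                    x = g_indices[ptr]
                    if x == other:
                        continue
                    fx = fg[x]
                    mx = 1 if cg[x] == ch[fx] else 0
                    if _has_edge(h_indptr, h_indices, old_img, fx):
                        d_mc[ma_old + mx] -= 1
                    if _has_edge(h_indptr, h_indices, new_img, fx):
                        d_mc[ma_new + mx] += 1
            if _has_edge(g_indptr, g_indices, u, v) and \
                    _has_edge(h_indptr, h_indices, fu, fv):
                mu = 1 if cg[u] == ch[fu] else 0
                mv = 1 if cg[v] == ch[fv] else 0
                d_mc[mu + mv] -= 1
                mu = 1 if cg[u] == ch[fv] else 0
                mv = 1 if cg[v] == ch[fu] else 0
                d_mc[mu + mv] += 1
            d_sim = sim[u, fv] + sim[v, fu] - sim[u, fu] - sim[v, fv]
            new_obj = _objective(alpha, wnum, wden, mc + d_mc, eind,
                                 mg, sim_sum + d_sim, n_g)
            d = new_obj - obj
            if d >= 0.0 or np.random.random() < np.exp(d / T):
                mc += d_mc
                sim_sum += d_sim
                obj = new_obj
                fg[u] = fv
                fg[v] = fu
                gh[fv] = u
                gh[fu] = v
    return obj
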