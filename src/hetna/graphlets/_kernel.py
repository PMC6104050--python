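"""Enumeration kernel for connected induced subgraphs on 2..5 nodes.

Each connected node subset is visited exactly once using the
exclusive-neighborhood extension rule (every subset is discovered from
its minimum node, and a candidate may only enter the extension set
through the first subset node it is adjacent to).  Subsets are
classified by an O(1) lookup in the precomputed labeled-mask orbit
tables, and counts are binned per (touched node, orbit, color
combination).

The numba-compiled kernel is the production path; ``_count_python``
implements the identical algorithm in pure Python and serves as a
fallback when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
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
def _find_ptr(indptr, indices, row, target):
    """Index into ``indices`` of ``target`` within ``row``'s sorted slice, or -1."""
    lo = indptr[row]
    hi = indptr[row + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        v = indices[mid]
        if v == target:
            return mid
        if v < target:
            lo = mid + 1
        else:
            hi = mid
    return -1


@njit(cache=True)
def _esu_count(indptr, indices, node_bit, edge_bit,
               t2, t3, t4, t5,
               max_size, ncombo_n, ncombo_e,
               counts_n, counts_e, want_n, want_e):
    n = len(indptr) - 1
    maxdeg = 0
    for v in range(n):
        d = indptr[v + 1] - indptr[v]
        if d > maxdeg:
            maxdeg = d
    cap = 5 * maxdeg + 8

    sub = np.empty(5, dtype=np.int64)
    extbuf = np.empty((5, cap), dtype=np.int64)
    cnt = np.empty(5, dtype=np.int64)
    idx = np.empty(5, dtype=np.int64)
    masks = np.empty(5, dtype=np.int64)
    ncomb = np.empty(5, dtype=np.int64)
    ecomb = np.empty(5, dtype=np.int64)

    for v in range(n):
        sub[0] = v
        c0 = 0
        for ptr in range(indptr[v], indptr[v + 1]):
            u = indices[ptr]
            if u > v:
                extbuf[0, c0] = u
                c0 += 1
        cnt[0] = c0
        idx[0] = 0
        masks[0] = 0
        ncomb[0] = node_bit[v]
        ecomb[0] = 0
        d = 0
        while d >= 0:
            if idx[d] < cnt[d]:
                w = extbuf[d, idx[d]]
                idx[d] += 1
                s = d + 2  # size after adding w
                m = masks[d]
                ec = ecomb[d]
                for i in range(d + 1):
                    ptr = _find_ptr(indptr, indices, w, sub[i])
                    if ptr >= 0:
                        m |= 1 << ((d + 1) * d // 2 + i)
                        ec |= edge_bit[ptr]
                nc = ncomb[d] | node_bit[w]
                sub[d + 1] = w

                # classify and record
                for p in range(s):
                    if s == 2:
                        o = t2[m, p]
                    elif s == 3:
                        o = t3[m, p]
                    elif s == 4:
                        o = t4[m, p]
                    else:
                        o = t5[m, p]
                    node = sub[p]
                    if want_n:
                        counts_n[node, o * ncombo_n + (nc - 1)] += 1
                    if want_e:
                        counts_e[node, o * ncombo_e + (ec - 1)] += 1

                if s < max_size:
                    c = 0
                    for t in range(idx[d], cnt[d]):
                        extbuf[d + 1, c] = extbuf[d, t]
                        c += 1
                    for ptr in range(indptr[w], indptr[w + 1]):
                        u = indices[ptr]
                        if u <= v:
                            continue
                        ok = True
                        for i in range(d + 1):
                            if u == sub[i] or _find_ptr(indptr, indices, sub[i], u) >= 0:
                                ok = False
                                break
                        if ok:
                            extbuf[d + 1, c] = u
                            c += 1
                    cnt[d + 1] = c
                    idx[d + 1] = 0
                    masks[d + 1] = m
                    ncomb[d + 1] = nc
                    ecomb[d + 1] = ec
                    d += 1
            else:
                d -= 1


def _count_python(indptr, indices, node_bit, edge_bit, tables,
                  max_size, ncombo_n, ncombo_e,
                  counts_n, counts_e, want_n, want_e):
    """Pure-Python mirror of ``_esu_count`` (same traversal, same bins)."""
    n = len(indptr) - 1
    adj = [set(indices[indptr[v]:indptr[v + 1]]) for v in range(n)]
    eb = {}
    for v in range(n):
        for ptr in range(indptr[v], indptr[v + 1]):
            eb[(v, int(indices[ptr]))] = int(edge_bit[ptr])

    def extend(sub, ext, mask, nc, ec, v):
        while ext:
            w = ext.pop()
            d = len(sub) - 1
            m, e = mask, ec
            for i, x in enumerate(sub):
                if w in adj[x]:
                    m |= 1 << ((d + 1) * d // 2 + i)
                    e |= eb[(x, w)]
            nc2 = nc | int(node_bit[w])
            sub2 = sub + [w]
            s = len(sub2)
            tab = tables[s]
            for p, node in enumerate(sub2):
                o = int(tab[m, p])
                if want_n:
                    counts_n[node, o * ncombo_n + (nc2 - 1)] += 1
                if want_e:
                    counts_e[node, o * ncombo_e + (e - 1)] += 1
            if s < max_size:
                ext2 = list(ext)
                for u in adj[w]:
                    if u <= v or u in sub2:
                        continue
                    if any(u in adj[x] for x in sub):
                        continue
                    ext2.append(int(u))
                extend(sub2, ext2, m, nc2, e, v)

    for v in range(n):
        ext = [int(u) for u in adj[v] if u > v]
        extend([v], ext, 0, int(node_bit[v]), 0, v)
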