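"""Per-node graphlet degree vectors, homogeneous and colored.

The homogeneous GDV counts, for every node, the induced occurrences of
each 2-5-node graphlet touched at each automorphism orbit.  The colored
variants (NCGDV / ECGDV) run the same enumeration once and additionally
bin each occurrence by the *set* of node (or edge) colors present in it,
so the per-orbit columns fan out into ``2**k - 1`` color-combination
columns while the enumeration cost stays independent of ``k``.
Marginalizing a colored vector over its combinations recovers the
homogeneous GDV exactly.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ..netmodel import ColoredNetwork
from . import _kernel
from .catalog import build_catalog

__all__ = [
    "count_gdv",
    "count_ncgdv",
    "count_ecgdv",
    "concat_signatures",
    "combo_label",
]

MAX_COLORS = 16


def _csr(net: ColoredNetwork):
    """CSR adjacency over nodes in sorted order, plus the node order."""
    nodes = net.nodes
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    indptr = np.zeros(n + 1, dtype=np.int64)
    for i, u in enumerate(nodes):
        indptr[i + 1] = indptr[i] + net.degree(u)
    indices = np.empty(indptr[-1], dtype=np.int64)
    for i, u in enumerate(nodes):
        nbrs = sorted(index[v] for v in net.neighbors(u))
        indices[indptr[i]:indptr[i + 1]] = nbrs
    return nodes, index, indptr, indices


def combo_label(combo_bits: int, colors: Sequence[str]) -> str:
    members = [c for i, c in enumerate(colors) if combo_bits >> i & 1]
    return "+".join(members)


def _column_labels(n_orbits: int, colors: Sequence[str], prefix: str) -> list:
    k = len(colors)
    if k == 0:
        return [f"o{o}" for o in range(n_orbits)]
    return [
        f"o{o}|{prefix}:{combo_label(c, colors)}"
        for o in range(n_orbits)
        for c in range(1, 2**k)
    ]


def _run_kernel(net, node_bit, edge_bit, max_size, ncombo_n, ncombo_e,
                want_n, want_e, engine):
    nodes, index, indptr, indices = _csr(net)
    cat = build_catalog(5)  # tables cover all sizes; max_size prunes depth
    n = len(nodes)
    counts_n = np.zeros((n, 73 * ncombo_n if want_n else 1), dtype=np.int64)
    counts_e = np.zeros((n, 73 * ncombo_e if want_e else 1), dtype=np.int64)

    use_numba = _kernel.HAVE_NUMBA if engine == "auto" else (engine == "numba")
    if use_numba and not _kernel.HAVE_NUMBA:
        raise RuntimeError("numba engine requested but numba is unavailable")
    if use_numba:
        _kernel._esu_count(
            indptr, indices, node_bit, edge_bit,
            cat.orbit_table[2], cat.orbit_table[3],
            cat.orbit_table[4], cat.orbit_table[5],
            max_size, ncombo_n, ncombo_e,
            counts_n, counts_e, want_n, want_e,
        )
    else:
        _kernel._count_python(
            indptr, indices, node_bit, edge_bit, cat.orbit_table,
            max_size, ncombo_n, ncombo_e,
            counts_n, counts_e, want_n, want_e,
        )
    return nodes, counts_n, counts_e


def _node_bits(net: ColoredNetwork, colors: Optional[Sequence[str]]):
    if colors is None:
        colors = net.colors
    colors = list(colors)
    if len(colors) != len(set(colors)):
        raise ValueError("duplicate entries in color list")
    if len(colors) > MAX_COLORS:
        raise ValueError(f"at most {MAX_COLORS} colors supported, got {len(colors)}")
    missing = set(net.node_color.values()) - set(colors)
    if missing:
        raise ValueError(f"network uses colors not in the declared set: {sorted(missing)}")
    cidx = {c: i for i, c in enumerate(colors)}
    bits = np.array([1 << cidx[net.node_color[u]] for u in net.nodes], dtype=np.int64)
    return colors, bits


def count_gdv(net: ColoredNetwork, max_size: int = 5, engine: str = "auto") -> pd.DataFrame:
    """Homogeneous graphlet degree vectors: one row per node, 73 orbit columns."""
    _check_net(net, max_size)
    node_bit = np.ones(net.n_nodes, dtype=np.int64)
    edge_bit = np.ones(2 * net.n_edges, dtype=np.int64)
    nodes, counts_n, _ = _run_kernel(net, node_bit, edge_bit, max_size,
                                     1, 1, True, False, engine)
    return pd.DataFrame(counts_n, index=list(nodes),
                        columns=[f"o{o}" for o in range(73)])


def count_ncgdv(net: ColoredNetwork, colors: Optional[Sequence[str]] = None,
                max_size: int = 5, engine: str = "auto") -> pd.DataFrame:
    """Node-colored GDVs: 73 * (2**k - 1) columns over the declared color set."""
    _check_net(net, max_size)
    colors, node_bit = _node_bits(net, colors)
    ncombo = 2 ** len(colors) - 1
    edge_bit = np.ones(2 * net.n_edges, dtype=np.int64)
    nodes, counts_n, _ = _run_kernel(net, node_bit, edge_bit, max_size,
                                     ncombo, 1, True, False, engine)
    return pd.DataFrame(counts_n, index=list(nodes),
                        columns=_column_labels(73, colors, "n"))


def count_ecgdv(net: ColoredNetwork, edge_colors: Optional[Sequence[str]] = None,
                max_size: int = 5, engine: str = "auto") -> pd.DataFrame:
    """Edge-colored GDVs, binned by the set of edge colors in each occurrence."""
    _check_net(net, max_size)
    if net.edge_color is None:
        raise ValueError("network has no edge colors; ECGDV undefined")
    if edge_colors is None:
        edge_colors = net.edge_colors
    edge_colors = list(edge_colors)
    if len(edge_colors) > MAX_COLORS:
        raise ValueError(f"at most {MAX_COLORS} edge colors supported")
    missing = set(net.edge_color.values()) - set(edge_colors)
    if missing:
        raise ValueError(f"network uses edge colors not in the declared set: {sorted(missing)}")
    eidx = {c: i for i, c in enumerate(edge_colors)}

    nodes, index, indptr, indices = _csr(net)
    edge_bit = np.empty(len(indices), dtype=np.int64)
    for i, u in enumerate(nodes):
        for ptr in range(indptr[i], indptr[i + 1]):
            v = nodes[indices[ptr]]
            key = (u, v) if u <= v else (v, u)
            edge_bit[ptr] = 1 << eidx[net.edge_color[key]]

    node_bit = np.ones(net.n_nodes, dtype=np.int64)
    ncombo_e = 2 ** len(edge_colors) - 1
    nodes, _, counts_e = _run_kernel(net, node_bit, edge_bit, max_size,
                                     1, ncombo_e, False, True, engine)
    return pd.DataFrame(counts_e, index=list(nodes),
                        columns=_column_labels(73, edge_colors, "e"))


def concat_signatures(ncgdv: pd.DataFrame, ecgdv: pd.DataFrame) -> pd.DataFrame:
    """Column-wise concatenation of two signature matrices (same node order)."""
    if ecgdv.shape[1] == 0:
        return ncgdv.copy()
    if list(ncgdv.index) != list(ecgdv.index):
        raise ValueError("signature matrices cover different node sets/orders")
    return pd.concat([ncgdv, ecgdv], axis=1)


def _check_net(net: ColoredNetwork, max_size: int) -> None:
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    if not (2 <= max_size <= 5):
        raise ValueError(f"max_size must be in 2..5, got {max_size}")
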