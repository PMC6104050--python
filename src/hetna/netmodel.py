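"""Core data model for colored networks plus all plain-text I/O.

Networks are simple and undirected.  Every node carries exactly one color
label; edges may optionally carry a color label as well.  All file formats
are whitespace-separated text: edge lists and alignments are 2-column,
node-color files are 2-column, edge-color files are 3-column
(node1, node2, color), and similarity files are 3-column
(node1, node2, similarity in [0, 1]).  Lines starting with ``#`` are
treated as comments everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, Mapping, Optional, Tuple

import networkx as nx

__all__ = [
    "ColoredNetwork",
    "TrueMapping",
    "Alignment",
    "SimilarityMatrix",
    "ParseError",
    "DEFAULT_COLOR",
    "read_network",
    "write_network",
    "read_alignment",
    "write_alignment",
    "read_similarity",
    "write_similarity",
    "read_true_mapping",
    "write_true_mapping",
]

DEFAULT_COLOR = "c1"

Edge = Tuple[str, str]


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _norm_edge(u: str, v: str) -> Edge:
    return (u, v) if u <= v else (v, u)


class ColoredNetwork:
    """A simple undirected graph with a total node→color map.

    Parameters
    ----------
    edges:
        Iterable of 2-tuples of node identifiers (strings).  Duplicate
        edges are collapsed; self-loops raise ``ValueError``.
    node_color:
        Optional mapping node → color label.  Nodes missing from the map
        (including nodes that appear only in ``edges``) default to
        ``DEFAULT_COLOR``, so a bare edge list yields a 1-colored network.
    edge_color:
        Optional mapping edge (any orientation) → color label.  When
        given, it must cover every edge.
    nodes:
        Optional iterable of extra (possibly isolated) nodes.
    """

    def __init__(
        self,
        edges: Iterable[Edge],
        node_color: Optional[Mapping[str, str]] = None,
        edge_color: Optional[Mapping[Edge, str]] = None,
        nodes: Optional[Iterable[str]] = None,
    ):
        adj: Dict[str, set] = {}
        edge_set: set = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise ValueError(f"self-loop {u!r}-{v!r} not allowed")
            e = _norm_edge(u, v)
            if e in edge_set:
                continue
            edge_set.add(e)
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        if nodes is not None:
            for nd in nodes:
                adj.setdefault(str(nd), set())
        if node_color is not None:
            for nd in node_color:
                adj.setdefault(str(nd), set())

        self._adj = adj
        self._edges = edge_set
        self._nodes = tuple(sorted(adj))

        nc = dict(node_color) if node_color else {}
        self.node_color: Dict[str, str] = {
            nd: str(nc.get(nd, DEFAULT_COLOR)) for nd in self._nodes
        }

        self.edge_color: Optional[Dict[Edge, str]] = None
        if edge_color is not None:
            norm = {}
            for (u, v), c in edge_color.items():
                norm[_norm_edge(str(u), str(v))] = str(c)
            missing = edge_set - set(norm)
            if missing:
                raise ValueError(f"edge_color missing {len(missing)} edges, e.g. {sorted(missing)[0]}")
            self.edge_color = {e: norm[e] for e in sorted(edge_set)}

    # -- basic accessors -------------------------------------------------

    @property
    def nodes(self) -> Tuple[str, ...]:
        return self._nodes

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edges(self) -> Iterator[Edge]:
        return iter(sorted(self._edges))

    def has_edge(self, u: str, v: str) -> bool:
        return _norm_edge(u, v) in self._edges

    def neighbors(self, u: str):
        return self._adj[u]

    def degree(self, u: str) -> int:
        return len(self._adj[u])

    @property
    def colors(self) -> Tuple[str, ...]:
        """Sorted distinct node color labels present in the network."""
        return tuple(sorted(set(self.node_color.values())))

    @property
    def k(self) -> int:
        return len(self.colors)

    @property
    def edge_colors(self) -> Tuple[str, ...]:
        if self.edge_color is None:
            return ()
        return tuple(sorted(set(self.edge_color.values())))

    def with_node_colors(self, node_color: Mapping[str, str]) -> "ColoredNetwork":
        """Copy of this network with a replacement node-color map."""
        unknown = set(node_color) - set(self._nodes)
        if unknown:
            raise ValueError(f"unknown nodes in color map: {sorted(unknown)[:3]}")
        return ColoredNetwork(self._edges, node_color=node_color,
                              edge_color=self.edge_color, nodes=self._nodes)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self._edges)
        return g

    def __eq__(self, other):
        if not isinstance(other, ColoredNetwork):
            return NotImplemented
        return (
            self._nodes == other._nodes
            and self._edges == other._edges
            and self.node_color == other.node_color
            and self.edge_color == other.edge_color
        )

    def __repr__(self):
        ec = f", |edge colors|={len(self.edge_colors)}" if self.edge_color else ""
        return (f"ColoredNetwork(n={self.n_nodes}, m={self.n_edges}, "
                f"k={self.k}{ec})")


@dataclass(frozen=True)
class TrueMapping:
    """Known ground-truth bijection between a network and its noisy copy."""

    pairs: Mapping[str, str]

    def __post_init__(self):
        vals = set(self.pairs.values())
        if len(vals) != len(self.pairs):
            raise ValueError("true mapping is not injective")

    def __getitem__(self, u: str) -> str:
        return self.pairs[u]

    def __len__(self):
        return len(self.pairs)


@dataclass
class Alignment:
    """Injective node mapping from the smaller network into the larger one."""

    mapping: Dict[str, str]
    method: Optional[str] = None
    seed: Optional[int] = None
    objective: Optional[float] = None

    def __post_init__(self):
        self.mapping = {str(u): str(v) for u, v in self.mapping.items()}
        images = set(self.mapping.values())
        if len(images) != len(self.mapping):
            raise ValueError("alignment is not injective")

    def __getitem__(self, u: str) -> str:
        return self.mapping[u]

    def __len__(self):
        return len(self.mapping)

    def items(self):
        return self.mapping.items()


class SimilarityMatrix:
    """Dense cross-network node similarity with values in [0, 1]."""

    def __init__(self, nodes_g, nodes_h, values):
        import numpy as np

        self.nodes_g = tuple(str(x) for x in nodes_g)
        self.nodes_h = tuple(str(x) for x in nodes_h)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.nodes_g), len(self.nodes_h)):
            raise ValueError("similarity matrix shape mismatch")
        self._ig = {u: i for i, u in enumerate(self.nodes_g)}
        self._ih = {v: j for j, v in enumerate(self.nodes_h)}

    def get(self, u: str, v: str) -> float:
        return float(self.values[self._ig[u], self._ih[v]])

    @property
    def shape(self):
        return self.values.shape

    def transpose(self) -> "SimilarityMatrix":
        return SimilarityMatrix(self.nodes_h, self.nodes_g, self.values.T)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _data_lines(path) -> Iterator[Tuple[int, list]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def read_network(
    edge_list_path,
    node_color_path=None,
    edge_color_path=None,
) -> ColoredNetwork:
    """Read a network from a 2-column edge list plus optional color files."""
    edges = []
    for lineno, parts in _data_lines(edge_list_path):
        if len(parts) != 2:
            raise ParseError(edge_list_path, lineno, f"expected 2 columns, got {len(parts)}")
        u, v = parts
        if u == v:
            raise ParseError(edge_list_path, lineno, f"self-loop on node {u!r}")
        edges.append((u, v))

    known = {n for e in edges for n in e}

    node_color = None
    if node_color_path is not None:
        node_color = {}
        for lineno, parts in _data_lines(node_color_path):
            if len(parts) != 2:
                raise ParseError(node_color_path, lineno, f"expected 2 columns, got {len(parts)}")
            nd, col = parts
            if nd not in known:
                raise ParseError(node_color_path, lineno, f"unknown node {nd!r}")
            node_color[nd] = col

    edge_color = None
    if edge_color_path is not None:
        edge_color = {}
        edge_set = {_norm_edge(u, v) for u, v in edges}
        for lineno, parts in _data_lines(edge_color_path):
            if len(parts) != 3:
                raise ParseError(edge_color_path, lineno, f"expected 3 columns, got {len(parts)}")
            u, v, col = parts
            if _norm_edge(u, v) not in edge_set:
                raise ParseError(edge_color_path, lineno, f"unknown edge {u!r}-{v!r}")
            edge_color[(u, v)] = col
        missing = edge_set - set(edge_color)
        if missing:
            raise ParseError(edge_color_path, 0,
                             f"edge-color file missing {len(missing)} edges, e.g. {sorted(missing)[0]}")

    return ColoredNetwork(edges, node_color=node_color, edge_color=edge_color)


def write_network(net: ColoredNetwork, edge_list_path,
                  node_color_path=None, edge_color_path=None,
                  header: str = "") -> None:
    with open(edge_list_path, "w") as fh:
        if header:
            fh.write(header)
        for u, v in net.edges():
            fh.write(f"{u}\t{v}\n")
    if node_color_path is not None:
        with open(node_color_path, "w") as fh:
            for nd in net.nodes:
                fh.write(f"{nd}\t{net.node_color[nd]}\n")
    if edge_color_path is not None:
        if net.edge_color is None:
            raise ValueError("network has no edge colors to write")
        with open(edge_color_path, "w") as fh:
            for (u, v), c in net.edge_color.items():
                fh.write(f"{u}\t{v}\t{c}\n")


def write_alignment(alignment: Alignment, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for u in sorted(alignment.mapping):
            fh.write(f"{u}\t{alignment.mapping[u]}\n")


def read_alignment(path) -> Alignment:
    mapping = {}
    for lineno, parts in _data_lines(path):
        if len(parts) != 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(parts)}")
        u, v = parts
        if u in mapping:
            raise ParseError(path, lineno, f"duplicate source node {u!r}")
        mapping[u] = v
    return Alignment(mapping)


def write_true_mapping(truth: TrueMapping, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for u in sorted(truth.pairs):
            fh.write(f"{u}\t{truth.pairs[u]}\n")


def read_true_mapping(path) -> TrueMapping:
    pairs = {}
    for lineno, parts in _data_lines(path):
        if len(parts) != 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(parts)}")
        pairs[parts[0]] = parts[1]
    return TrueMapping(pairs)


def write_similarity(sim: SimilarityMatrix, path, header: str = "") -> None:
    """Write a 3-column (node1, node2, similarity) file, 6 decimal digits."""
    import numpy as np

    if np.any(sim.values < 0) or np.any(sim.values > 1):
        raise ValueError("similarity values must lie in [0, 1]")
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for i, u in enumerate(sim.nodes_g):
            row = sim.values[i]
            for j, v in enumerate(sim.nodes_h):
                fh.write(f"{u}\t{v}\t{row[j]:.6f}\n")


def read_similarity(path) -> SimilarityMatrix:
    import numpy as np

    entries = {}
    for lineno, parts in _data_lines(path):
        if len(parts) != 3:
            raise ParseError(path, lineno, f"expected 3 columns, got {len(parts)}")
        u, v, s = parts
        try:
            val = float(s)
        except ValueError:
            raise ParseError(path, lineno, f"bad similarity value {s!r}") from None
        if not (0.0 <= val <= 1.0):
            raise ParseError(path, lineno, f"similarity {val} outside [0, 1]")
        entries[(u, v)] = val
    nodes_g = tuple(sorted({u for u, _ in entries}))
    nodes_h = tuple(sorted({v for _, v in entries}))
    values = np.zeros((len(nodes_g), len(nodes_h)))
    ig = {u: i for i, u in enumerate(nodes_g)}
    ih = {v: j for j, v in enumerate(nodes_h)}
    for (u, v), s in entries.items():
        values[ig[u], ih[v]] = s
    return SimilarityMatrix(nodes_g, nodes_h, values)
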