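"""Edge-conservation classification and S3 scoring, plain and color-aware.

An edge of the smaller network G is *conserved* under an alignment f when
its image pair is an edge of the larger network H; non-conserved edges
are G-edges mapped onto H non-edges plus H-edges joining two image nodes
whose preimages are non-adjacent in G.  The homogeneous S3 score is
conserved / (conserved + non-conserved).  The heterogeneous variant
down-weights each conserved edge by how many of its two aligned endpoint
pairs agree in color: weight 1 with both matching, 2/3 with one, 1/3
with none (configurable), and uses the same ratio with the weighted
conserved total in place of the raw count.

``SearchState`` maintains the tallies incrementally so that search
aligners can evaluate swap / change moves in O(degree) time;
``delta_objective`` is exact against a from-scratch recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Optional, Tuple, Union

from .netmodel import Alignment, ColoredNetwork, SimilarityMatrix

__all__ = [
    "ConservationSummary",
    "DEFAULT_WEIGHTS",
    "classify_edges",
    "hom_s3",
    "het_s3",
    "combined_objective",
    "SearchState",
    "delta_objective",
    "apply_move",
]

# conservation weight by number of matching endpoint-color pairs (2, 1, 0)
DEFAULT_WEIGHTS: Tuple[Fraction, Fraction, Fraction] = (
    Fraction(1), Fraction(2, 3), Fraction(1, 3))
HOMOGENEOUS_WEIGHTS: Tuple[Fraction, Fraction, Fraction] = (
    Fraction(1), Fraction(1), Fraction(1))


def _as_fractions(weights) -> Tuple[Fraction, Fraction, Fraction]:
    out = []
    for w in weights:
        out.append(w if isinstance(w, Fraction) else Fraction(w).limit_denominator(10**6))
    if len(out) != 3:
        raise ValueError("expected 3 conservation weights (2, 1, 0 color matches)")
    return tuple(out)


@dataclass(frozen=True)
class ConservationSummary:
    """Tallies of conserved edges (by endpoint color matches) and non-conserved edges."""

    weight_full: int        # conserved, both endpoint colors match
    weight_partial: int     # conserved, exactly one endpoint color matches
    weight_least: int       # conserved, no endpoint color matches
    n_nonconserved: int

    @property
    def n_conserved(self) -> int:
        return self.weight_full + self.weight_partial + self.weight_least

    def total_weight(self, weights=DEFAULT_WEIGHTS) -> Fraction:
        w2, w1, w0 = _as_fractions(weights)
        return (w2 * self.weight_full + w1 * self.weight_partial
                + w0 * self.weight_least)


def _mapping_of(f: Union[Alignment, Dict[str, str]]) -> Dict[str, str]:
    return f.mapping if isinstance(f, Alignment) else dict(f)


def classify_edges(G: ColoredNetwork, H: ColoredNetwork,
                   f: Union[Alignment, Dict[str, str]]) -> ConservationSummary:
    """Classify edges under an alignment from G (smaller) into H."""
    mapping = _mapping_of(f)
    if set(mapping) != set(G.nodes):
        raise ValueError("alignment is not total on the source network's nodes")
    images = set(mapping.values())
    if len(images) != len(mapping):
        raise ValueError("alignment is not injective")
    unknown = images - set(H.nodes)
    if unknown:
        raise ValueError(f"alignment images missing from target network: {sorted(unknown)[:3]}")

    full = partial = least = 0
    conserved = 0
    for u, v in G.edges():
        fu, fv = mapping[u], mapping[v]
        if H.has_edge(fu, fv):
            conserved += 1
            matches = int(G.node_color[u] == H.node_color[fu]) + \
                int(G.node_color[v] == H.node_color[fv])
            if matches == 2:
                full += 1
            elif matches == 1:
                partial += 1
            else:
                least += 1

    # H-side edges induced on the image set
    e_induced = 0
    for x, y in H.edges():
        if x in images and y in images:
            e_induced += 1

    n_noncons = (G.n_edges - conserved) + (e_induced - conserved)
    return ConservationSummary(full, partial, least, n_noncons)


def hom_s3(summary: ConservationSummary) -> float:
    denom = summary.n_conserved + summary.n_nonconserved
    if denom == 0:
        raise ValueError("S3 undefined: no conserved or non-conserved edges")
    return summary.n_conserved / denom


def het_s3(summary: ConservationSummary, weights=DEFAULT_WEIGHTS) -> float:
    total = summary.total_weight(weights)
    denom = total + summary.n_nonconserved
    if denom == 0:
        raise ValueError("S3 undefined: no conserved or non-conserved edges")
    return float(total / denom)


def combined_objective(G: ColoredNetwork, H: ColoredNetwork,
                       f: Union[Alignment, Dict[str, str]],
                       sim: SimilarityMatrix,
                       alpha: float = 0.5,
                       ec_measure: str = "hets3",
                       weights=DEFAULT_WEIGHTS) -> float:
    """alpha * NC + (1 - alpha) * EC, with NC the mean aligned-pair similarity."""
    mapping = _mapping_of(f)
    summary = classify_edges(G, H, mapping)
    if ec_measure == "hets3":
        ec = het_s3(summary, weights)
    elif ec_measure == "homs3":
        ec = hom_s3(summary)
    else:
        raise ValueError(f"unknown ec_measure {ec_measure!r}")
    nc = sum(sim.get(u, v) for u, v in mapping.items()) / len(mapping)
    return alpha * nc + (1.0 - alpha) * ec


# ---------------------------------------------------------------------------
# incremental search state
# ---------------------------------------------------------------------------

Move = Tuple  # ("swap", u, v) or ("change", u, new_image)


class SearchState:
    """Alignment state with O(degree) incremental objective updates.

    Tracks, for the current injective mapping f: V(G) -> V(H):
    conserved-edge counts per color-match class (exact integers), the
    number of H edges induced on the image set, and the aligned-pair
    similarity sum.  ``ec_measure="homs3"`` is realised as unit weights.
    """

    def __init__(self, G: ColoredNetwork, H: ColoredNetwork,
                 sim: SimilarityMatrix, f: Union[Alignment, Dict[str, str]],
                 alpha: float = 0.5, ec_measure: str = "hets3",
                 weights=DEFAULT_WEIGHTS):
        if G.n_nodes > H.n_nodes:
            raise ValueError("source network must not be larger than the target")
        if G.n_edges == 0:
            raise ValueError("source network has no edges; EC undefined")
        if ec_measure == "homs3":
            weights = HOMOGENEOUS_WEIGHTS
        elif ec_measure != "hets3":
            raise ValueError(f"unknown ec_measure {ec_measure!r}")
        self.G, self.H, self.sim = G, H, sim
        self.alpha = float(alpha)
        self.ec_measure = ec_measure
        self.weights = _as_fractions(weights)
        self.f: Dict[str, str] = dict(_mapping_of(f))
        if set(self.f) != set(G.nodes):
            raise ValueError("alignment is not total on the source network")
        self.inv: Dict[str, str] = {}
        for u, x in self.f.items():
            if x in self.inv:
                raise ValueError("alignment is not injective")
            self.inv[x] = u

        self.m_g = G.n_edges
        self.match_counts = [0, 0, 0]  # index = number of color matches
        for u, v in G.edges():
            fu, fv = self.f[u], self.f[v]
            if H.has_edge(fu, fv):
                self.match_counts[self._matches(u, fu) + self._matches(v, fv)] += 1
        self.e_induced = sum(
            1 for x, y in H.edges() if x in self.inv and y in self.inv)
        self.sim_sum = sum(sim.get(u, x) for u, x in self.f.items())

    # -- helpers ---------------------------------------------------------

    def _matches(self, u: str, x: str) -> int:
        return int(self.G.node_color[u] == self.H.node_color[x])

    def _edge_stats(self, u, v, fu, fv):
        """(conserved?, match class) of G-edge (u, v) under images (fu, fv)."""
        if not self.H.has_edge(fu, fv):
            return 0, 0
        return 1, self._matches(u, fu) + self._matches(v, fv)

    def _objective_from(self, match_counts, e_induced, sim_sum) -> float:
        w2, w1, w0 = self.weights
        total = w0 * match_counts[0] + w1 * match_counts[1] + w2 * match_counts[2]
        conserved = sum(match_counts)
        noncons = (self.m_g - conserved) + (e_induced - conserved)
        denom = total + noncons
        ec = float(total / denom) if denom != 0 else 0.0
        nc = sim_sum / len(self.f)
        return self.alpha * nc + (1.0 - self.alpha) * ec

    def objective(self) -> float:
        return self._objective_from(self.match_counts, self.e_induced, self.sim_sum)

    # -- move evaluation -------------------------------------------------

    def _move_delta(self, move: Move):
        """Hypothetical tallies after `move` without mutating the state."""
        kind = move[0]
        mc = list(self.match_counts)
        e_ind = self.e_induced
        sim_sum = self.sim_sum
        G, H, f = self.G, self.H, self.f

        if kind == "swap":
            _, u, v = move
            if u not in f or v not in f or u == v:
                raise ValueError(f"illegal swap move {move!r}")
            fu, fv = f[u], f[v]
            for a, old_img, new_img, other in ((u, fu, fv, v), (v, fv, fu, u)):
                for x in G.neighbors(a):
                    if x == other:
                        continue
                    c, m = self._edge_stats(a, x, old_img, f[x])
                    if c:
                        mc[m] -= 1
                    c, m = self._edge_stats(a, x, new_img, f[x])
                    if c:
                        mc[m] += 1
            if G.has_edge(u, v):
                c, m = self._edge_stats(u, v, fu, fv)
                if c:
                    mc[m] -= 1
                c, m = self._edge_stats(u, v, fv, fu)
                if c:
                    mc[m] += 1
            sim_sum += (self.sim.get(u, fv) + self.sim.get(v, fu)
                        - self.sim.get(u, fu) - self.sim.get(v, fv))
        elif kind == "change":
            _, u, h_new = move
            if u not in f:
                raise ValueError(f"illegal change move {move!r}: unknown source")
            if h_new in self.inv:
                raise ValueError(f"illegal change move {move!r}: image in use")
            if h_new not in self.H.node_color:
                raise ValueError(f"illegal change move {move!r}: unknown target node")
            old = f[u]
            for x in G.neighbors(u):
                c, m = self._edge_stats(u, x, old, f[x])
                if c:
                    mc[m] -= 1
                c, m = self._edge_stats(u, x, h_new, f[x])
                if c:
                    mc[m] += 1
            e_ind -= sum(1 for y in H.neighbors(old) if y in self.inv)
            e_ind += sum(1 for y in H.neighbors(h_new) if y in self.inv and y != old)
            sim_sum += self.sim.get(u, h_new) - self.sim.get(u, old)
        else:
            raise ValueError(f"unknown move kind {kind!r}")
        return mc, e_ind, sim_sum

    def delta_objective(self, move: Move) -> float:
        """Exact objective change if `move` were applied."""
        mc, e_ind, sim_sum = self._move_delta(move)
        return self._objective_from(mc, e_ind, sim_sum) - self.objective()

    def apply(self, move: Move) -> None:
        mc, e_ind, sim_sum = self._move_delta(move)
        self.match_counts, self.e_induced, self.sim_sum = mc, e_ind, sim_sum
        if move[0] == "swap":
            _, u, v = move
            self.f[u], self.f[v] = self.f[v], self.f[u]
            self.inv[self.f[u]] = u
            self.inv[self.f[v]] = v
        else:
            _, u, h_new = move
            old = self.f[u]
            del self.inv[old]
            self.f[u] = h_new
            self.inv[h_new] = u

    def summary(self) -> ConservationSummary:
        conserved = sum(self.match_counts)
        noncons = (self.m_g - conserved) + (self.e_induced - conserved)
        return ConservationSummary(self.match_counts[2], self.match_counts[1],
                                   self.match_counts[0], noncons)


def delta_objective(state: SearchState, move: Move) -> float:
    """Module-level convenience wrapper around ``SearchState.delta_objective``."""
    return state.delta_objective(move)


def apply_move(state: SearchState, move: Move) -> None:
    state.apply(move)
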