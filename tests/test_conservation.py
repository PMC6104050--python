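from fractions import Fraction

import numpy as np
import pytest

from hetna.conservation import (
    ConservationSummary,
    SearchState,
    classify_edges,
    combined_objective,
    het_s3,
    hom_s3,
)
from hetna.netmodel import Alignment, ColoredNetwork, SimilarityMatrix

from conftest import random_colored_network


def random_sim(g, h, seed):
    rng = np.random.default_rng(seed)
    return SimilarityMatrix(g.nodes, h.nodes,
                            rng.random((g.n_nodes, h.n_nodes)))


def random_state(seed, n_g=8, n_h=10, k=2, ec_measure="hets3"):
    rng = np.random.default_rng(seed)
    G = random_colored_network(n_g, 0.45, k, seed=seed)
    H = random_colored_network(n_h, 0.45, k, seed=seed + 1000)
    sim = random_sim(G, H, seed + 2000)
    images = list(H.nodes)
    rng.shuffle(images)
    f = dict(zip(G.nodes, images))
    return SearchState(G, H, sim, f, ec_measure=ec_measure), rng


class TestWorkedExample:
    def test_homogeneous_tally(self, fig3_instance):
        G, H, f = fig3_instance
        s = classify_edges(G, H, f)
        assert s.n_conserved == 4
        assert s.n_nonconserved == 2
        assert hom_s3(s) == pytest.approx(4 / 6)
        assert round(hom_s3(s), 2) == 0.67

    def test_heterogeneous_tally(self, fig3_instance):
        G, H, f = fig3_instance
        s = classify_edges(G, H, f)
        assert (s.weight_full, s.weight_partial, s.weight_least) == (1, 2, 1)
        assert s.total_weight() == Fraction(8, 3)
        assert het_s3(s) == pytest.approx(float(Fraction(8, 3) / (Fraction(8, 3) + 2)))
        assert round(het_s3(s), 2) == 0.57


class TestClassification:
    def test_self_alignment_all_full(self):
        net = random_colored_network(10, 0.4, 2, seed=1)
        f = {u: u for u in net.nodes}
        s = classify_edges(net, net, f)
        assert s.n_conserved == net.n_edges
        assert s.n_nonconserved == 0
        assert s.weight_full == net.n_edges
        assert hom_s3(s) == 1.0

    def test_no_conserved_edges(self):
        G = ColoredNetwork([("a", "b")], nodes=["a", "b"])
        H = ColoredNetwork([("x", "z")], nodes=["x", "y", "z"])
        s = classify_edges(G, H, {"a": "x", "b": "y"})
        assert s.n_conserved == 0
        assert s.n_nonconserved == 1
        assert hom_s3(s) == 0.0

    def test_h_side_nonconserved_counted_once(self, fig3_instance):
        # a-d (G side) and b'-c' (H side) each contribute exactly one
        G, H, f = fig3_instance
        assert classify_edges(G, H, f).n_nonconserved == 2

    def test_non_total_rejected(self, fig3_instance):
        G, H, f = fig3_instance
        with pytest.raises(ValueError, match="total"):
            classify_edges(G, H, {"a": "a'"})

    def test_non_injective_rejected(self, fig3_instance):
        G, H, _ = fig3_instance
        bad = {"a": "a'", "b": "a'", "c": "c'", "d": "d'"}
        with pytest.raises(ValueError, match="injective"):
            classify_edges(G, H, bad)

    def test_zero_denominator_is_error(self):
        G = ColoredNetwork([], nodes=["a"])
        H = ColoredNetwork([], nodes=["x"])
        s = classify_edges(G, H, {"a": "x"})
        with pytest.raises(ValueError, match="undefined"):
            hom_s3(s)
        with pytest.raises(ValueError, match="undefined"):
            het_s3(s)


class TestHetS3Properties:
    def test_reduces_to_hom_with_one_color(self):
        G = random_colored_network(9, 0.4, 1, seed=3)
        H = random_colored_network(11, 0.4, 1, seed=4)
        f = dict(zip(G.nodes, H.nodes))
        s = classify_edges(G, H, f)
        assert het_s3(s) == pytest.approx(hom_s3(s))

    def test_closed_form_for_all_mismatched(self):
        # c conserved edges with zero color matches, m non-conserved
        for c, m in [(3, 2), (1, 5), (4, 0)]:
            s = ConservationSummary(0, 0, c, m)
            assert het_s3(s) == pytest.approx((c / 3) / ((c / 3) + m))

    def test_het_never_exceeds_hom(self):
        for seed in range(8):
            G = random_colored_network(8, 0.45, 3, seed=seed)
            H = random_colored_network(10, 0.45, 3, seed=seed + 50)
            f = dict(zip(G.nodes, np.random.default_rng(seed).permutation(H.nodes)[:G.n_nodes]))
            s = classify_edges(G, H, f)
            if s.n_conserved + s.n_nonconserved == 0:
                continue
            assert het_s3(s) <= hom_s3(s) + 1e-12
            if s.n_conserved == s.weight_full:
                assert het_s3(s) == pytest.approx(hom_s3(s))

    def test_custom_weights(self, fig3_instance):
        G, H, f = fig3_instance
        s = classify_edges(G, H, f)
        assert het_s3(s, weights=(1, 1, 1)) == pytest.approx(hom_s3(s))


class TestSearchState:
    def test_objective_matches_combined_objective(self):
        state, _ = random_state(0)
        expect = combined_objective(state.G, state.H, dict(state.f), state.sim)
        assert state.objective() == pytest.approx(expect, abs=1e-12)

    def test_swap_then_swap_back_is_zero(self):
        state, rng = random_state(1)
        nodes = list(state.f)
        u, v = nodes[0], nodes[3]
        before = state.objective()
        state.apply(("swap", u, v))
        state.apply(("swap", u, v))
        assert state.objective() == pytest.approx(before, abs=1e-12)
        assert state.f == random_state(1)[0].f

    def test_delta_equals_full_recompute(self):
        state, rng = random_state(2)
        nodes = list(state.f)
        for _ in range(150):
            unused = [x for x in state.H.nodes if x not in state.inv]
            if unused and rng.random() < 0.5:
                move = ("change", nodes[rng.integers(len(nodes))],
                        unused[rng.integers(len(unused))])
            else:
                i, j = rng.choice(len(nodes), size=2, replace=False)
                move = ("swap", nodes[i], nodes[j])
            before = combined_objective(state.G, state.H, dict(state.f), state.sim)
            d = state.delta_objective(move)
            state.apply(move)
            after = combined_objective(state.G, state.H, dict(state.f), state.sim)
            assert d == pytest.approx(after - before, abs=1e-9)
            assert state.objective() == pytest.approx(after, abs=1e-9)

    def test_delta_with_hom_measure(self):
        state, rng = random_state(3, ec_measure="homs3")
        nodes = list(state.f)
        for _ in range(50):
            i, j = rng.choice(len(nodes), size=2, replace=False)
            move = ("swap", nodes[i], nodes[j])
            before = combined_objective(state.G, state.H, dict(state.f),
                                        state.sim, ec_measure="homs3")
            d = state.delta_objective(move)
            state.apply(move)
            after = combined_objective(state.G, state.H, dict(state.f),
                                       state.sim, ec_measure="homs3")
            assert d == pytest.approx(after - before, abs=1e-9)

    def test_illegal_moves_rejected(self):
        state, _ = random_state(4)
        u = next(iter(state.f))
        used_image = state.f[u]
        with pytest.raises(ValueError, match="image in use"):
            state.delta_objective(("change", u, used_image))
        with pytest.raises(ValueError, match="illegal swap"):
            state.delta_objective(("swap", u, u))
        with pytest.raises(ValueError, match="unknown move"):
            state.delta_objective(("teleport", u, u))

    def test_change_to_isolated_image(self):
        # change to an image with no edges among aligned nodes: EC delta
        # reflects only the lost incidences of the old image
        G = ColoredNetwork([("a", "b"), ("b", "c")])
        H = ColoredNetwork([("x", "y"), ("y", "z")], nodes=["x", "y", "z", "w"])
        sim = SimilarityMatrix(G.nodes, H.nodes, np.full((3, 4), 0.5))
        state = SearchState(G, H, sim, {"a": "x", "b": "y", "c": "z"})
        s0 = state.summary()
        assert s0.n_conserved == 2
        d = state.delta_objective(("change", "c", "w"))
        state.apply(("change", "c", "w"))
        s1 = state.summary()
        assert s1.n_conserved == 1          # b-c no longer conserved
        assert state.e_induced == 1         # y-z left the induced image
        assert d == pytest.approx(state.objective() - combined_objective(
            G, H, {"a": "x", "b": "y", "c": "z"}, sim), abs=1e-12)

    def test_summary_consistent_with_classify(self):
        state, _ = random_state(5)
        expect = classify_edges(state.G, state.H, dict(state.f))
        assert state.summary() == expect
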