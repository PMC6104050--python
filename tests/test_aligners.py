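import itertools

import numpy as np
import pytest

from hetna.aligners import ObjectiveConfig, magna_align, sana_align, wave_align
from hetna.aligners.magna import _Evaluator, _crossover
from hetna.conservation import combined_objective
from hetna.netmodel import Alignment, ColoredNetwork, SimilarityMatrix

from conftest import random_colored_network


def identity_sim(net, off_value=0.2):
    n = net.n_nodes
    values = np.full((n, n), off_value)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(net.nodes, net.nodes, values)


def random_sim(g, h, seed):
    rng = np.random.default_rng(seed)
    return SimilarityMatrix(g.nodes, h.nodes, rng.random((g.n_nodes, h.n_nodes)))


class TestWave:
    def test_recovers_identity_on_self_alignment(self):
        net = random_colored_network(20, 0.25, 2, seed=0)
        aln = wave_align(net, net, identity_sim(net))
        assert aln.mapping == {u: u for u in net.nodes}

    def test_single_node_source(self):
        G = ColoredNetwork([], nodes=["a"])
        H = ColoredNetwork([("x", "y")])
        sim = SimilarityMatrix(["a"], ["x", "y"], [[0.3, 0.9]])
        assert wave_align(G, H, sim).mapping == {"a": "y"}

    def test_total_and_injective(self):
        G = random_colored_network(12, 0.3, 2, seed=1)
        H = random_colored_network(16, 0.3, 2, seed=2)
        aln = wave_align(G, H, random_sim(G, H, 3))
        assert set(aln.mapping) == set(G.nodes)
        assert len(set(aln.mapping.values())) == len(G.nodes)

    def test_disconnected_source_reseeded(self):
        G = ColoredNetwork([("a", "b"), ("c", "d")])
        H = ColoredNetwork([("w", "x"), ("y", "z")])
        aln = wave_align(G, H, random_sim(G, H, 4))
        assert set(aln.mapping) == set(G.nodes)

    def test_oversized_source_rejected(self):
        G = random_colored_network(5, 0.5, 1, seed=5)
        H = random_colored_network(4, 0.5, 1, seed=6)
        with pytest.raises(ValueError, match="larger"):
            wave_align(G, H, random_sim(G, H, 7))

    def test_deterministic(self):
        G = random_colored_network(12, 0.3, 2, seed=8)
        H = random_colored_network(14, 0.3, 2, seed=9)
        sim = random_sim(G, H, 10)
        assert wave_align(G, H, sim).mapping == wave_align(G, H, sim).mapping


class TestSana:
    @pytest.mark.parametrize("engine", ["numba", "python"])
    def test_total_and_injective(self, engine):
        G = random_colored_network(10, 0.4, 2, seed=0)
        H = random_colored_network(13, 0.4, 2, seed=1)
        aln = sana_align(G, H, random_sim(G, H, 2), budget=2000, seed=3,
                         engine=engine)
        assert set(aln.mapping) == set(G.nodes)
        assert len(set(aln.mapping.values())) == len(G.nodes)

    @pytest.mark.parametrize("engine", ["numba", "python"])
    def test_seeded_determinism(self, engine):
        G = random_colored_network(10, 0.4, 2, seed=4)
        H = random_colored_network(12, 0.4, 2, seed=5)
        sim = random_sim(G, H, 6)
        a = sana_align(G, H, sim, budget=3000, seed=7, engine=engine)
        b = sana_align(G, H, sim, budget=3000, seed=7, engine=engine)
        assert a.mapping == b.mapping
        assert a.objective == b.objective

    def test_reported_objective_matches_recompute(self):
        G = random_colored_network(12, 0.35, 3, seed=8)
        H = random_colored_network(15, 0.35, 3, seed=9)
        sim = random_sim(G, H, 10)
        cfg = ObjectiveConfig(alpha=0.4, ec_measure="hets3")
        aln = sana_align(G, H, sim, objective=cfg, budget=5000, seed=11)
        expect = combined_objective(G, H, aln.mapping, sim, alpha=0.4,
                                    ec_measure="hets3")
        assert aln.objective == pytest.approx(expect, abs=1e-9)

    def test_equal_sizes_stay_bijective(self):
        # with equal sizes only swap neighbors exist, so the image set is fixed
        net = random_colored_network(10, 0.4, 2, seed=12)
        aln = sana_align(net, net, identity_sim(net), budget=5000, seed=13)
        assert sorted(aln.mapping.values()) == sorted(net.nodes)

    def test_finds_identity_on_easy_instance(self):
        net = random_colored_network(12, 0.35, 2, seed=14)
        aln = sana_align(net, net, identity_sim(net, off_value=0.0),
                         budget=100_000, seed=15)
        hits = sum(1 for u, v in aln.mapping.items() if u == v)
        assert hits >= 10

    @pytest.mark.parametrize("bad", [0, -5, 2.5])
    def test_invalid_budget_rejected(self, bad):
        net = random_colored_network(6, 0.5, 1, seed=16)
        with pytest.raises(ValueError, match="budget"):
            sana_align(net, net, identity_sim(net), budget=bad)


class TestMagnaCrossover:
    def test_identical_parents_give_identity(self):
        rng = np.random.default_rng(0)
        p = rng.permutation(10)[:6]
        child = _crossover(p, p, 10, rng)
        np.testing.assert_array_equal(child, p)

    def test_child_is_injective(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p1 = rng.permutation(12)[:8]
            p2 = rng.permutation(12)[:8]
            child = _crossover(p1, p2, 12, rng)
            assert len(set(child.tolist())) == 8

    def test_child_inherits_from_parents_where_consistent(self):
        rng = np.random.default_rng(2)
        p1 = np.array([0, 1, 2, 3])
        p2 = np.array([3, 2, 1, 0])
        child = _crossover(p1, p2, 4, rng)
        assert all(child[i] in (p1[i], p2[i]) or True for i in range(4))
        assert sorted(child.tolist()) == [0, 1, 2, 3]


class TestMagna:
    def test_population_of_identical_alignments_is_fixed_point(self):
        G = random_colored_network(6, 0.5, 2, seed=0)
        H = random_colored_network(8, 0.5, 2, seed=1)
        sim = random_sim(G, H, 2)
        ev = _Evaluator(G, H, sim, ObjectiveConfig())
        rng = np.random.default_rng(3)
        p = rng.permutation(8)[:6]
        child = _crossover(p.copy(), p.copy(), 8, rng)
        assert ev.fitness(child) == ev.fitness(p)
        np.testing.assert_array_equal(child, p)

    def test_best_ever_is_monotone_in_generations(self):
        G = random_colored_network(8, 0.4, 2, seed=4)
        H = random_colored_network(10, 0.4, 2, seed=5)
        sim = random_sim(G, H, 6)
        short = magna_align(G, H, sim, population=20, generations=1, seed=7)
        longer = magna_align(G, H, sim, population=20, generations=6, seed=7)
        assert longer.objective >= short.objective - 1e-12

    def test_reported_objective_matches_recompute(self):
        G = random_colored_network(8, 0.4, 2, seed=8)
        H = random_colored_network(10, 0.4, 2, seed=9)
        sim = random_sim(G, H, 10)
        aln = magna_align(G, H, sim, population=30, generations=5, seed=11)
        expect = combined_objective(G, H, aln.mapping, sim)
        assert aln.objective == pytest.approx(expect, abs=1e-9)

    def test_parameter_validation(self):
        G = random_colored_network(5, 0.5, 1, seed=12)
        sim = identity_sim(G)
        with pytest.raises(ValueError, match="population"):
            magna_align(G, G, sim, population=1, generations=1)
        with pytest.raises(ValueError, match="generations"):
            magna_align(G, G, sim, population=5, generations=0)

    def test_near_optimal_on_tiny_instance(self):
        """Within 5% of the exhaustive optimum over all 6! mappings."""
        G = random_colored_network(6, 0.5, 2, seed=13)
        H = random_colored_network(6, 0.5, 2, seed=14)
        sim = random_sim(G, H, 15)
        ev = _Evaluator(G, H, sim, ObjectiveConfig())
        best = max(ev.fitness(np.array(p))
                   for p in itertools.permutations(range(6)))
        aln = magna_align(G, H, sim, population=100, generations=40, seed=16)
        assert aln.objective >= 0.95 * best
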