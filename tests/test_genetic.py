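"""Genetic-algorithm operators, the evolve loop, and the GA-BP hybrid."""

import numpy as np
import pytest

from lqci.genetic import (GABPRegressor, GAConfig, crossover, decode, encode,
                          evolve, fitness, ga_bp_train, mutate,
                          select_roulette)
from lqci.network import (NetworkTopology, TrainConfig, error_E, init_params,
                          train_bp)


class _ScriptedRng:
    """Stub RNG whose random() returns a scripted sequence."""

    def __init__(self, seq):
        self.seq = list(seq)

    def random(self, size=None):
        if size is None:
            return self.seq.pop(0)
        raise NotImplementedError


class TestEncoding:
    def test_round_trip_identity(self, rng):
        t = NetworkTopology(3, 4, 2)
        p = init_params(t, rng)
        q = decode(encode(p), t)
        for name in ("v1", "b1", "w2", "b2"):
            assert np.array_equal(getattr(p, name), getattr(q, name))

    def test_gene_count_2_2_1(self):
        assert NetworkTopology(2, 2, 1).n_genes == 9

    def test_study_topology_gene_count(self):
        assert NetworkTopology(17, 6, 1).n_genes == 115

    def test_zero_chromosome_decodes_to_zero_params(self):
        t = NetworkTopology(2, 3, 1)
        p = decode(np.zeros(t.n_genes), t)
        assert not p.v1.any() and not p.b1.any()
        assert not p.w2.any() and not p.b2.any()

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            decode(np.zeros(7), NetworkTopology(2, 2, 1))


class TestFitness:
    def test_limits(self, rng):
        t = NetworkTopology(2, 2, 1)
        p = init_params(t, rng)
        X = rng.uniform(0, 1, (3, 2))
        from lqci.network import forward
        y = forward(p, X)          # E = 0
        assert fitness(encode(p), X, y, t) == pytest.approx(1.0)

    def test_matches_error_module(self, rng):
        t = NetworkTopology(3, 2, 1)
        c = rng.uniform(-1, 1, t.n_genes)
        X = rng.uniform(0, 1, (4, 3))
        y = rng.uniform(0.2, 0.8, (4, 1))
        e = error_E(decode(c, t), X, y)
        assert fitness(c, X, y, t) == pytest.approx(1.0 / (1.0 + e))
        if abs(e - 1.0) < 1:  # fitness strictly decreasing in E around here
            assert fitness(c, X, y, t) < 1.0


class TestRoulette:
    def test_uniform_fitness_uniform_selection(self):
        rng = np.random.default_rng(0)
        pop = np.arange(4)[:, None].astype(float)
        counts = np.zeros(4)
        for _ in range(20_000):
            counts[int(select_roulette(pop, np.ones(4), rng)[0])] += 1
        freq = counts / counts.sum()
        assert np.allclose(freq, 0.25, atol=3 * np.sqrt(0.25 * 0.75 / 20_000))

    def test_3_to_1_odds(self):
        rng = np.random.default_rng(1)
        pop = np.array([[0.0], [1.0]])
        n = 100_000
        first = sum(select_roulette(pop, np.array([3.0, 1.0]), rng)[0] == 0.0
                    for _ in range(n))
        p = 0.75
        assert abs(first / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_single_member_always_selected(self):
        rng = np.random.default_rng(2)
        pop = np.array([[0.7]])
        assert select_roulette(pop, np.array([0.4]), rng)[0] == 0.7

    def test_zero_fitness_rejected(self):
        with pytest.raises(ValueError):
            select_roulette(np.zeros((2, 1)), np.zeros(2),
                            np.random.default_rng(0))


class TestCrossover:
    def test_pe_zero_copies_parents(self, rng):
        a, b = rng.uniform(-1, 1, 5), rng.uniform(-1, 1, 5)
        ca, cb = crossover(a, b, 0.0, rng)
        assert np.array_equal(ca, a) and np.array_equal(cb, b)

    def test_identical_parents_fixed_point(self, rng):
        a = rng.uniform(-1, 1, 6)
        ca, cb = crossover(a, a.copy(), 1.0, rng)
        assert np.allclose(ca, a) and np.allclose(cb, a)

    def test_forced_midpoint_hand_arithmetic(self):
        rng = _ScriptedRng([0.0, 0.5])  # trigger crossover, alpha = 0.5
        a = np.array([0.2, -0.6, 1.0])
        b = np.array([0.4, 0.0, -1.0])
        ca, cb = crossover(a, b, 0.3, rng)
        assert np.allclose(ca, [0.3, -0.3, 0.0])
        assert np.allclose(cb, [0.3, -0.3, 0.0])

    def test_children_within_bounds(self, rng):
        for _ in range(50):
            a = rng.uniform(-1, 1, 8)
            b = rng.uniform(-1, 1, 8)
            ca, cb = crossover(a, b, 1.0, rng)
            assert np.all(np.abs(ca) <= 1) and np.all(np.abs(cb) <= 1)


class TestMutate:
    def test_pm_zero_identity(self, rng):
        c = rng.uniform(-1, 1, 10)
        assert np.array_equal(mutate(c, 0.0, rng), c)

    def test_pm_one_uniform_distribution(self):
        from scipy import stats
        rng = np.random.default_rng(4)
        draws = mutate(np.zeros(10_000), 1.0, rng)
        assert np.all(np.abs(draws) < 1)
        ks = stats.kstest(draws, stats.uniform(loc=-1, scale=2).cdf)
        assert ks.pvalue > 0.01

    def test_seeded_reproducible(self):
        c = np.linspace(-0.9, 0.9, 12)
        a = mutate(c, 0.5, np.random.default_rng(7))
        b = mutate(c, 0.5, np.random.default_rng(7))
        assert np.array_equal(a, b)


class TestEvolve:
    def _toy(self, rng):
        t = NetworkTopology(1, 1, 1)
        X = np.array([[0.0], [0.5], [1.0]])
        y = np.array([[0.3], [0.5], [0.7]])
        return t, X, y

    def test_gen_zero_returns_best_of_initial_population(self, rng):
        t, X, y = self._toy(rng)
        cfg = GAConfig(population_size=10, generations=0, seed=3)
        best, hist = evolve(X, y, t, cfg)
        assert len(hist) == 1
        # recompute: best must dominate a fresh draw of the same population
        pop = np.random.default_rng(3).uniform(-1, 1, (10, t.n_genes))
        fits = [fitness(c, X, y, t) for c in pop]
        assert hist[0].best_fitness == pytest.approx(max(fits))
        assert np.array_equal(best, pop[int(np.argmax(fits))])

    def test_elitism_makes_best_fitness_monotone(self, rng):
        t, X, y = self._toy(rng)
        cfg = GAConfig(population_size=8, generations=30, elitism_count=1,
                       seed=11)
        _, hist = evolve(X, y, t, cfg)
        best = [h.best_fitness for h in hist]
        assert all(b >= a for a, b in zip(best, best[1:]))

    def test_reaches_near_bp_optimum_on_realisable_toy_problem(self):
        # targets generated by a network whose exact parameters lie inside
        # the gene bounds, so E = 0 is attainable; 200 generations of GA
        # alone should land within 10x of the BP-converged error (median
        # over 10 seeds)
        from lqci.network import NetworkParams, forward

        t = NetworkTopology(1, 1, 1)
        p_true = NetworkParams(np.array([[0.8]]), np.array([-0.4]),
                               np.array([[0.6]]), np.array([-0.3]))
        X = np.linspace(0, 1, 5)[:, None]
        y = forward(p_true, X)
        cfg_bp = TrainConfig(learning_rate=0.5, target_error=1e-6,
                             max_epochs=50_000, momentum=0.9)
        ga_es, bp_es = [], []
        for seed in range(10):
            best, hist = evolve(X, y, t, GAConfig(
                population_size=20, generations=200, seed=seed))
            _, h_bp = train_bp(decode(best, t), X, y, cfg_bp)
            ga_es.append(hist[-1].best_E)
            bp_es.append(h_bp[-1])
        assert np.median(ga_es) <= 10 * np.median(bp_es)

    def test_all_generations_within_bounds(self, rng):
        t, X, y = self._toy(rng)
        cfg = GAConfig(population_size=6, generations=10, seed=2)
        best, _ = evolve(X, y, t, cfg)
        assert np.all(np.abs(best) <= 1)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=1)
        with pytest.raises(ValueError):
            GAConfig(crossover_prob=1.5)
        with pytest.raises(ValueError):
            GAConfig(elitism_count=20, population_size=20)


class TestGABPTrain:
    def test_bp_refinement_never_worse_than_ga_best(self, rng):
        t = NetworkTopology(2, 2, 1)
        X = rng.uniform(0, 1, (5, 2))
        y = rng.uniform(0.3, 0.7, (5, 1))
        params, report = ga_bp_train(
            X, y, t, GAConfig(population_size=10, generations=20, seed=1),
            TrainConfig(learning_rate=0.1, target_error=1e-8,
                        max_epochs=5000))
        assert report["final_E"] <= report["ga_best_E"] + 1e-12

    def test_gen_zero_degenerates_to_bp_from_random_pick(self, rng):
        t = NetworkTopology(2, 2, 1)
        X = rng.uniform(0, 1, (4, 2))
        y = rng.uniform(0.3, 0.7, (4, 1))
        params, report = ga_bp_train(
            X, y, t, GAConfig(population_size=5, generations=0, seed=2),
            TrainConfig(max_epochs=100))
        assert len(report["ga_history"]) == 1


class TestGABPRegressor:
    def test_exposes_ga_trace_after_fit(self, study_data):
        X, y, _ = study_data
        est = GABPRegressor(generations=5, population_size=6,
                            max_epochs=500, random_state=0)
        est.fit(X, y)
        assert len(est.ga_history_) == 6
        assert est.ga_best_E_ == est.ga_history_[-1].best_E
        best = [h.best_fitness for h in est.ga_history_]
        assert all(b >= a for a, b in zip(best, best[1:]))

    def test_whole_pipeline_reproducible_under_master_seed(self, study_data):
        X, y, _ = study_data
        kw = dict(generations=3, population_size=5, max_epochs=300,
                  random_state=42)
        a = GABPRegressor(**kw).fit(X, y).predict(X)
        b = GABPRegressor(**kw).fit(X, y).predict(X)
        assert np.array_equal(a, b)
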