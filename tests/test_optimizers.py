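"""Contract tests for the three metaheuristics: decode, Levy steps, convergence."""

import math

import numpy as np
import pytest

from metathresh import (
    CuckooParams,
    HarmonyParams,
    OptimizerConfig,
    SearchSpace,
    brute_force_optimum,
    decode,
    levy_step,
    make_objective,
    mantegna_sigma,
    optimize,
)
from metathresh.optimizers import _pool_insert

from conftest import random_gmm_histogram

SPHERE_CENTER = np.array([60.0, 180.0])


def sphere(th):
    """Maximized at th == SPHERE_CENTER (strictly increasing, inside bounds)."""
    return -float(np.sum((th - SPHERE_CENTER) ** 2))


class TestDecode:
    def test_round_and_keep_order(self):
        space = SearchSpace(dim=2, lower=1, upper=254)
        assert decode(np.array([12.4, 200.7]), space).tolist() == [12, 201]

    def test_duplicate_repair_increments_upward(self):
        space = SearchSpace(dim=2, lower=1, upper=254)
        # (100.2, 99.8) -> round (100, 100) -> sort -> repair -> (100, 101)
        assert decode(np.array([100.2, 99.8]), space).tolist() == [100, 101]

    def test_out_of_bounds_clamped(self):
        space = SearchSpace(dim=2, lower=1, upper=254)
        assert decode(np.array([-3.0, 300.0]), space).tolist() == [1, 254]

    def test_collision_at_upper_bound_resolves_downward(self):
        space = SearchSpace(dim=3, lower=1, upper=254)
        assert decode(np.array([254.0, 254.0, 254.0]), space).tolist() == [252, 253, 254]

    def test_result_always_valid(self):
        space = SearchSpace(dim=4, lower=1, upper=14)
        rng = np.random.default_rng(0)
        for _ in range(200):
            th = decode(rng.uniform(-5, 20, size=4), space)
            assert (np.diff(th) > 0).all()
            assert th[0] >= 1 and th[-1] <= 14

    def test_more_thresholds_than_levels_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            decode(np.arange(20.0), SearchSpace(dim=20, lower=1, upper=14))


class TestLevyStep:
    def test_mantegna_sigma_matches_gamma_formula(self):
        # frozen from direct evaluation of the Gamma-ratio expression at beta=1.5
        assert mantegna_sigma(1.5) == pytest.approx(0.696575, abs=1e-6)
        beta = 1.2
        expected = (
            math.gamma(1 + beta)
            * math.sin(math.pi * beta / 2)
            / (math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
        ) ** (1 / beta)
        assert mantegna_sigma(beta) == pytest.approx(expected, rel=1e-12)

    def test_heavier_tail_than_gaussian(self):
        rng = np.random.default_rng(42)
        steps = levy_step(1.5, rng, size=100_000)
        sigma = mantegna_sigma(1.5)
        tail = np.mean(np.abs(steps) > 3 * sigma)
        assert tail > 0.0027  # Gaussian 3-sigma mass

    def test_beta_2_finite_variance_regime(self):
        rng = np.random.default_rng(7)
        steps = levy_step(2.0, rng, size=100_000)
        # at the Gaussian end of the family the tail is far lighter than beta=1.5
        rng2 = np.random.default_rng(7)
        heavy = levy_step(1.2, rng2, size=100_000)
        q = 0.999
        assert np.quantile(np.abs(steps), q) < np.quantile(np.abs(heavy), q)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            mantegna_sigma(2.5)


class TestSphereConvergence:
    """All three algorithms locate a known unique optimum within 1 unit."""

    @pytest.mark.parametrize(
        "algorithm,pop,iters",
        [("cs", 25, 500), ("eo", 30, 500), ("hs", 20, 2000)],
    )
    def test_within_one_of_optimum(self, algorithm, pop, iters):
        space = SearchSpace(dim=2, lower=1, upper=254)
        cfg = OptimizerConfig(
            algorithm=algorithm,
            population_size=pop,
            max_iterations=iters,
            seed=1,
            hs=HarmonyParams(bw=2.0),
        )
        res = optimize(sphere, space, cfg)
        assert np.all(np.abs(res.best_thresholds - SPHERE_CENTER) <= 1.0)


class TestContract:
    @pytest.mark.parametrize("algorithm", ["cs", "eo", "hs"])
    def test_reproducible_and_elitist(self, algorithm, uniform16):
        f = make_objective(uniform16, "sef")
        space = SearchSpace.for_levels(1, 16)
        cfg = OptimizerConfig(
            algorithm=algorithm, population_size=8, max_iterations=40, seed=3
        )
        a = optimize(f, space, cfg)
        b = optimize(f, space, cfg)
        np.testing.assert_array_equal(a.history, b.history)  # bitwise
        np.testing.assert_array_equal(a.best_thresholds, b.best_thresholds)
        assert (np.diff(a.history) >= 0).all()
        assert a.best_fitness == a.history[-1]
        assert a.history.size == cfg.max_iterations
        assert a.seed == 3

    @pytest.mark.parametrize("algorithm", ["cs", "eo", "hs"])
    def test_every_evaluation_decodes_to_valid_thresholds(self, algorithm):
        h = random_gmm_histogram(5)
        inner = make_objective(h, "otsu")

        def checked(th):
            assert (np.diff(th) > 0).all() or th.size == 1
            assert th.min() >= 1 and th.max() <= 14
            assert np.issubdtype(th.dtype, np.integer)
            return inner(th)

        cfg = OptimizerConfig(algorithm=algorithm, population_size=6, max_iterations=30, seed=0)
        optimize(checked, SearchSpace.for_levels(2, 16), cfg)

    def test_budget_accounting(self, uniform16):
        f = make_objective(uniform16, "otsu")
        space = SearchSpace.for_levels(1, 16)
        pop, iters = 8, 25
        cs = optimize(f, space, OptimizerConfig("cs", pop, iters, seed=0))
        assert cs.evaluations == pop + iters * (pop + round(0.25 * pop))
        eo = optimize(f, space, OptimizerConfig("eo", pop, iters, seed=0))
        assert eo.evaluations == pop * (iters + 1)
        hs = optimize(f, space, OptimizerConfig("hs", pop, iters, seed=0))
        assert hs.evaluations == pop + iters

    def test_single_iteration_history(self, uniform16):
        f = make_objective(uniform16, "sef")
        res = optimize(
            f,
            SearchSpace.for_levels(1, 16),
            OptimizerConfig("cs", population_size=4, max_iterations=1, seed=0),
        )
        assert res.history.size == 1
        assert res.best_fitness == res.history[0]

    def test_non_finite_fitness_aborts_with_thresholds(self):
        def bad(th):
            return float("nan")

        with pytest.raises(ArithmeticError, match=r"\[.*\]"):
            optimize(
                bad,
                SearchSpace.for_levels(1, 16),
                OptimizerConfig("cs", population_size=4, max_iterations=1, seed=0),
            )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            OptimizerConfig(algorithm="pso")
        with pytest.raises(ValueError):
            OptimizerConfig(population_size=3)
        with pytest.raises(ValueError):
            CuckooParams(pa=1.5)
        with pytest.raises(ValueError):
            SearchSpace(dim=1, lower=5, upper=5)


class TestHarmonyOperators:
    def test_memory_only_mode_never_improves(self, uniform16):
        # HMCR=1, PAR=0: no new component values can enter the memory
        f = make_objective(uniform16, "sef")
        cfg = OptimizerConfig(
            "hs",
            population_size=6,
            max_iterations=50,
            seed=2,
            hs=HarmonyParams(hmcr=1.0, par=0.0),
        )
        res = optimize(f, SearchSpace.for_levels(1, 16), cfg)
        assert np.all(res.history == res.history[0])


class TestEquilibriumPool:
    def test_pool_keeps_four_best_in_order(self):
        pool_pos = np.zeros((4, 2))
        pool_fit = np.full(4, -np.inf)
        candidates = [(np.array([1.0, 2.0]), 5.0), (np.array([3.0, 4.0]), 9.0),
                      (np.array([5.0, 6.0]), 3.0), (np.array([7.0, 8.0]), 7.0),
                      (np.array([9.0, 1.0]), 1.0)]
        for pos, fit in candidates:
            _pool_insert(pool_pos, pool_fit, pos, fit)
        assert pool_fit.tolist() == [9.0, 7.0, 5.0, 3.0]
        # the attractor pool's fifth member is the component-wise mean of the four
        expected_mean = np.mean(
            [c[0] for c in sorted(candidates, key=lambda c: -c[1])[:4]], axis=0
        )
        np.testing.assert_allclose(pool_pos.mean(axis=0), expected_mean)

    @pytest.mark.parametrize("k", [1, 2])
    def test_matches_oracle_on_small_histograms(self, k):
        # spot check at a handful of seeds; the full-rate check is in acceptance
        hits = 0
        for seed in range(5):
            h = random_gmm_histogram(200 + seed)
            _, best = brute_force_optimum(h, k, "otsu")
            f = make_objective(h, "otsu")
            res = optimize(
                f,
                SearchSpace.for_levels(k, 16),
                OptimizerConfig("eo", population_size=15, max_iterations=100, seed=seed),
            )
            assert res.best_fitness <= best + 1e-12
            hits += abs(res.best_fitness - best) <= 1e-9
        assert hits >= 4
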