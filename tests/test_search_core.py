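"""Population machinery: initialization, evaluation, roles, Lévy flight,
seasonal monitoring and the generic run harness."""

import math

import numpy as np
import pytest
from scipy.special import gamma

from assoa import (
    ASSOAParams,
    SearchSpace,
    SSParams,
    assign_roles,
    evaluate_population,
    init_population,
    levy_sample,
    levy_sigma,
    run_optimizer,
    seasonal_constant,
    seasonal_minimum,
)
from assoa.baselines import GAParams, GWOParams
from assoa.core import CountingObjective, sphere
from assoa.errors import (
    ConfigurationError,
    EvaluationError,
    StaleFitnessError,
    UnknownAlgorithmError,
)
from assoa.space import Population


class TestSearchSpace:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            SearchSpace(dims=2, lower=np.array([0.0, 1.0]), upper=np.array([1.0, 1.0]))

    def test_clip(self, unit_square):
        clipped = unit_square.clip(np.array([-0.5, 1.5]))
        assert clipped.tolist() == [0.0, 1.0]


class TestInitPopulation:
    def test_positions_within_bounds(self, unit_square):
        pop = init_population(unit_square, 5, seed=0)
        assert pop.positions.shape == (5, 2)
        assert np.all(pop.positions >= 0.0) and np.all(pop.positions <= 1.0)
        assert np.all(pop.velocities == 0.0)

    def test_uniform_mean(self, box10):
        # law of large numbers: per-dimension sample mean within 3 SE of 0
        pop = init_population(box10, 100, seed=7)
        se = 10.0 / math.sqrt(12.0) / math.sqrt(100)
        assert np.all(np.abs(pop.positions.mean(axis=0)) < 3 * se)

    def test_too_few_agents(self, unit_square):
        with pytest.raises(ConfigurationError, match="5"):
            init_population(unit_square, 4, seed=0)

    def test_unset_fitness_reads_loudly(self, unit_square):
        pop = init_population(unit_square, 5, seed=0)
        with pytest.raises(StaleFitnessError):
            pop.best_index()


class TestEvaluatePopulation:
    def test_sphere_values(self, unit_square):
        pop = init_population(unit_square, 5, seed=0)
        pop.positions[0] = [0.0, 0.0]
        pop.positions[1] = [1.0, 1.0]
        evaluate_population(pop, sphere)
        assert pop.fitness[0] == 0.0
        assert pop.fitness[1] == pytest.approx(2.0)

    def test_counter_increments_by_n(self, box10):
        counting = CountingObjective(sphere)
        pop = init_population(box10, 10, seed=1)
        evaluate_population(pop, counting)
        assert counting.evaluations == 10

    def test_non_finite_objective_names_agent(self, unit_square):
        pop = init_population(unit_square, 5, seed=0)
        calls = iter([1.0, 1.0, float("nan")])

        with pytest.raises(EvaluationError, match="agent 2"):
            evaluate_population(pop, lambda x: next(calls))


class TestAssignRoles:
    def _pop(self, fitness):
        n = len(fitness)
        pop = Population(np.zeros((n, 2)), np.zeros((n, 2)), np.asarray(fitness, dtype=float))
        return pop

    def test_rank_partition(self):
        roles = assign_roles(self._pop([3.0, 1.0, 2.0, 5.0, 4.0]), rng=0)
        assert roles.hickory == 1
        assert set(roles.acorn) == {2, 0, 4}
        assert roles.normal.tolist() == [3]

    def test_index_tie_break(self):
        roles = assign_roles(self._pop([1.0] * 6), rng=0)
        assert roles.hickory == 0
        assert roles.acorn.tolist() == [1, 2, 3]

    def test_normal_partition_is_disjoint_cover(self):
        roles = assign_roles(self._pop(list(range(10))), rng=3)
        merged = sorted(np.concatenate([roles.n2_split, roles.n3_split]).tolist())
        assert merged == sorted(roles.normal.tolist())
        assert len(roles.n2_split) + len(roles.n3_split) == 6

    def test_hickory_is_global_best(self, rng):
        fitness = rng.normal(size=9)
        roles = assign_roles(self._pop(fitness), rng=rng)
        assert fitness[roles.hickory] == fitness.min()


class TestLevy:
    def test_sigma_beta_one_exactly_one(self):
        assert levy_sigma(1.0) == pytest.approx(1.0, abs=1e-15)

    def test_sigma_matches_closed_form(self):
        beta = 1.5
        expected = (
            gamma(1 + beta) * math.sin(math.pi * beta / 2)
            / (gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
        ) ** (1 / beta)
        assert levy_sigma(beta) == pytest.approx(expected, rel=1e-14)
        assert levy_sigma(beta) == pytest.approx(0.696575, abs=1e-6)

    @pytest.mark.parametrize("beta", [0.0, 2.5, -1.0])
    def test_sigma_domain(self, beta):
        with pytest.raises(ConfigurationError):
            levy_sigma(beta)

    def test_sample_shape_and_finiteness(self, rng):
        step = levy_sample(1.5, 3, rng)
        assert step.shape == (3,)
        assert np.isfinite(step).all()

    def test_forced_draws_hand_value(self):
        class Scripted:
            def __init__(self, values):
                self._values = iter(values)

            def uniform(self, *a, **k):
                return next(self._values)

        step = levy_sample(1.5, 1, Scripted([0.5, 0.5]))
        expected = 0.01 * 0.5 * levy_sigma(1.5) / 0.5 ** (2.0 / 3.0)
        assert step[0] == pytest.approx(expected, rel=1e-12)
        assert step[0] == pytest.approx(0.005528, abs=1e-6)

    def test_heavy_tail(self, rng):
        samples = np.abs(np.concatenate([levy_sample(1.5, 100, rng) for _ in range(100)]))
        assert np.median(samples) < np.quantile(samples, 0.99) / 10.0


class TestSeasonal:
    def _pop_roles(self, positions):
        n = len(positions)
        pop = Population(
            np.asarray(positions, dtype=float), np.zeros((n, len(positions[0]))),
            np.arange(n, dtype=float),
        )
        return pop, assign_roles(pop, rng=0)

    def test_zero_distance(self):
        pop, roles = self._pop_roles([[1.0, 1.0]] * 5)
        assert seasonal_constant(pop, roles).tolist() == [0.0, 0.0, 0.0]

    def test_three_four_five(self):
        pop, roles = self._pop_roles([[0.0, 0.0], [3.0, 4.0], [0.0, 0.0], [0.0, 0.0], [9.0, 9.0]])
        assert seasonal_constant(pop, roles)[0] == pytest.approx(5.0)

    def test_translation_invariance(self, rng):
        positions = rng.normal(size=(6, 3))
        pop, roles = self._pop_roles(positions.tolist())
        shifted, _ = self._pop_roles((positions + 17.5).tolist())
        np.testing.assert_allclose(
            seasonal_constant(pop, roles), seasonal_constant(shifted, roles), rtol=1e-9
        )

    def test_minimum_values(self):
        assert seasonal_minimum(0, 100) == pytest.approx(1e-6)
        assert seasonal_minimum(100, 100) == pytest.approx(1e-6 / 365.0**2.5, rel=1e-15)

    def test_minimum_decreasing(self):
        values = [seasonal_minimum(t, 50) for t in range(1, 51)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_zero_iterations_error(self):
        with pytest.raises(ConfigurationError):
            seasonal_minimum(1, 0)


PARAMS = {
    "assoa": ASSOAParams(n=12, t_m=30),
    "ss": SSParams(n=12, t_m=30),
    "gwo": GWOParams(n=12, t_m=30),
    "ga": GAParams(n=12, t_m=30),
}


class TestRunHarness:
    def test_unknown_algorithm_lists_registered(self, box10):
        with pytest.raises(UnknownAlgorithmError, match="assoa"):
            run_optimizer("simulated-annealing", box10, "sphere", SSParams(n=5, t_m=1), seed=0)

    @pytest.mark.parametrize("algorithm", sorted(PARAMS))
    def test_deterministic_given_seed(self, algorithm, box10):
        r1 = run_optimizer(algorithm, box10, "sphere", PARAMS[algorithm], seed=11)
        r2 = run_optimizer(algorithm, box10, "sphere", PARAMS[algorithm], seed=11)
        assert np.array_equal(r1.best_position, r2.best_position)
        assert np.array_equal(r1.curve, r2.curve)
        assert r1.best_fitness == r2.best_fitness

    @pytest.mark.parametrize("algorithm", sorted(PARAMS))
    @pytest.mark.parametrize("objective", ["sphere", "rastrigin"])
    def test_curve_non_increasing(self, algorithm, objective, box10):
        result = run_optimizer(algorithm, box10, objective, PARAMS[algorithm], seed=5)
        assert np.all(np.diff(result.curve) <= 0)
        assert result.best_fitness == result.curve[-1]

    def test_best_position_matches_best_fitness(self, box10):
        result = run_optimizer("assoa", box10, "sphere", PARAMS["assoa"], seed=3)
        assert sphere(result.best_position) == pytest.approx(result.best_fitness)

    def test_maximize_negates(self, box10):
        result = run_optimizer(
            "ss", box10, lambda x: -sphere(x), SSParams(n=8, t_m=10), seed=0, maximize=True
        )
        assert result.best_fitness <= 0.0  # max of -sphere is 0
        assert np.all(np.diff(result.curve) >= 0)
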