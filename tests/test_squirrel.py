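"""Squirrel-search update rules: gliding cases, the advanced moves, seasonal
relocation, and the degeneration of the advanced variant to the basic one."""

import numpy as np
import pytest

from assoa import (
    ASSOAParams,
    SearchSpace,
    SSParams,
    assign_roles,
    assoa_step,
    evaluate_population,
    glide_move,
    init_population,
    levy_sample,
    relocate_assoa,
    run_optimizer,
    ss_step,
)
from assoa.core import sphere
from assoa.errors import ConfigurationError
from assoa.squirrel import (
    BASIC_CASES,
    CASE_RANDOM,
    CASE_RELOCATE_SS,
)


class TestGlideMove:
    def test_fixed_point(self):
        x = np.array([0.3, 0.7])
        np.testing.assert_array_equal(glide_move(x, x, 0.8, 1.9), x)

    def test_hand_value(self):
        out = glide_move(np.zeros(2), np.ones(2), 1.0, 1.9)
        np.testing.assert_allclose(out, [1.9, 1.9])

    def test_linear_in_distance(self, rng):
        x = rng.normal(size=4)
        target = rng.normal(size=4)
        d1 = glide_move(x, target, 0.5, 1.9) - x
        d2 = glide_move(x, target, 1.0, 1.9) - x
        np.testing.assert_allclose(d2, 2.0 * d1, rtol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ConfigurationError):
            glide_move(np.zeros(2), np.zeros(3), 1.0, 1.9)


class TestRelocateAssoa:
    def test_fixed_point_at_hickory(self):
        x = np.array([2.0, -1.5])
        np.testing.assert_array_equal(relocate_assoa(x, x, 0.7), x)

    def test_hand_value(self):
        out = relocate_assoa(np.array([1.0]), np.array([2.0]), 0.5)
        assert out[0] == pytest.approx(-6.0)

    def test_zero_r_returns_hickory(self, rng):
        x_nt = rng.normal(size=3)
        x_ht = rng.normal(size=3)
        np.testing.assert_array_equal(relocate_assoa(x_nt, x_ht, 0.0), x_ht)

    def test_zero_denominator_guard(self):
        out = relocate_assoa(np.array([0.0]), np.array([1.0]), 0.5)
        assert np.isfinite(out).all()


def _evaluated_pop(space, n, seed):
    pop = init_population(space, n, seed)
    evaluate_population(pop, sphere)
    return pop


class TestSsStep:
    def test_no_random_branch_when_pdp_tiny(self, box10, rng):
        params = SSParams(n=10, t_m=50, P_dp=1e-12)
        pop = _evaluated_pop(box10, 10, rng)
        trace = []
        roles = assign_roles(pop, rng)
        ss_step(pop, roles, params, box10, sphere, 1, rng, trace)
        assert all(case != CASE_RANDOM for _, _, case in trace)

    def test_random_branch_when_pdp_near_one(self, box10, rng):
        params = SSParams(n=10, t_m=50, P_dp=1.0 - 1e-12)
        pop = _evaluated_pop(box10, 10, rng)
        trace = []
        roles = assign_roles(pop, rng)
        ss_step(pop, roles, params, box10, sphere, 1, rng, trace)
        moved = [case for _, _, case in trace if case != CASE_RELOCATE_SS]
        assert moved and all(case == CASE_RANDOM for case in moved)
        assert np.all(pop.positions >= box10.lower) and np.all(pop.positions <= box10.upper)

    def test_positions_stay_in_bounds(self, box10, rng):
        params = SSParams(n=12, t_m=20)
        pop = _evaluated_pop(box10, 12, rng)
        for t in range(1, 21):
            roles = assign_roles(pop, rng)
            ss_step(pop, roles, params, box10, sphere, t, rng)
            assert np.all(pop.positions >= box10.lower)
            assert np.all(pop.positions <= box10.upper)
            assert not np.isnan(pop.fitness).any()

    def test_seasonal_relocation_matches_levy_law(self, rng):
        """With the trigger forced, normals land at L + Levy * (U - L): the
        normalized coordinate must reproduce independent Lévy draws."""
        space = SearchSpace.box(4, -2.0, 6.0)
        params = SSParams(n=40, t_m=10)
        pop = _evaluated_pop(space, 40, rng)
        # force the trigger: put four agents at the optimum (they become
        # hickory + acorns, at mutual distance zero)
        order = np.argsort(pop.fitness)
        pop.positions[order[:4]] = 0.0
        evaluate_population(pop, sphere)
        roles = assign_roles(pop, rng)
        trace = []
        ss_step(pop, roles, params, space, sphere, 1, np.random.default_rng(9), trace)
        relocated = [agent for _, agent, case in trace if case == CASE_RELOCATE_SS]
        assert sorted(relocated) == sorted(roles.normal.tolist())
        coords = (pop.positions[roles.normal] - space.lower) / (space.upper - space.lower)
        oracle = np.concatenate(
            [levy_sample(1.5, 4, np.random.default_rng(1000 + i)) for i in range(36)]
        )
        # same heavy-tailed small-magnitude law (clipped at 1)
        assert np.median(coords) == pytest.approx(np.median(np.minimum(oracle, 1.0)), abs=0.01)


class TestAssoaStep:
    def test_glide_branch_only_basic_cases(self, box10, rng):
        params = ASSOAParams(n=10, t_m=50, p_pin=0.9)
        pop = _evaluated_pop(box10, 10, rng)
        roles = assign_roles(pop, rng)
        trace = []
        assoa_step(pop, roles, params, box10, sphere, 1, rng, trace)
        assert trace and all(case in BASIC_CASES for _, _, case in trace)

    def test_advanced_branch_moves_normals_only(self, box10, rng):
        params = ASSOAParams(n=10, t_m=50, p_pin=0.1)
        pop = _evaluated_pop(box10, 10, rng)
        roles = assign_roles(pop, rng)
        before = pop.positions.copy()
        trace = []
        assoa_step(pop, roles, params, box10, sphere, 1, rng, trace)
        moved_agents = {agent for _, agent, _ in trace}
        assert moved_agents <= set(roles.normal.tolist())
        np.testing.assert_array_equal(pop.positions[roles.hickory], before[roles.hickory])
        np.testing.assert_array_equal(pop.positions[roles.acorn], before[roles.acorn])

    def test_case_exclusivity(self, box10, rng):
        params = ASSOAParams(n=15, t_m=30)
        pop = _evaluated_pop(box10, 15, rng)
        for t in range(1, 31):
            roles = assign_roles(pop, rng)
            trace = []
            assoa_step(pop, roles, params, box10, sphere, t, rng, trace)
            agents = [agent for _, agent, _ in trace]
            assert len(agents) == len(set(agents))

    def test_case5_vertical_reaches_target(self):
        """Fitter random agent, zero velocity, coefficient forced to 1: the
        mover lands exactly on the random agent."""
        space = SearchSpace.box(2, -10.0, 10.0)
        positions = np.array(
            [[0.0, 0.0], [1.0, 1.0], [1.5, 0.5], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]]
        )
        pop = init_population(space, 6, seed=0)
        pop.positions = positions.copy()
        evaluate_population(pop, sphere)
        roles = assign_roles(pop, rng=0)

        class Scripted:
            """p, P_a, a, rand-agent index, P_d, d, then (c, r) per agent."""

            def __init__(self):
                self.uniform_draws = iter([0.1, 0.9, 0.1, 0.2, 0.9] + [1.0, 1.0] * 2)

            def uniform(self, *args, **kwargs):
                return next(self.uniform_draws)

            def integers(self, n):
                return 0  # pick the first normal agent (the fitter of the two)

        assoa_step(pop, roles, ASSOAParams(n=6, t_m=10), space, sphere, 1, Scripted())
        target = positions[roles.normal[0]]
        # the slower normal agent moved exactly onto the random (fitter) one
        np.testing.assert_allclose(pop.positions[roles.normal[1]], target, rtol=1e-12)

    def test_degenerates_to_ss_bit_identically(self, box10):
        """With the p-branch pinned high and shared rng streams, the advanced
        step reproduces the basic step exactly over 50 iterations."""
        params_ss = SSParams(n=12, t_m=50)
        params_assoa = ASSOAParams(n=12, t_m=50, p_pin=1.0)

        def run(step, params):
            rng = np.random.default_rng(42)
            pop = init_population(box10, params.n, rng)
            evaluate_population(pop, sphere)
            for t in range(1, 51):
                roles = assign_roles(pop, rng)
                step(pop, roles, params, box10, sphere, t, rng)
            return pop

        p_ss = run(ss_step, params_ss)
        p_assoa = run(assoa_step, params_assoa)
        assert np.array_equal(p_ss.positions, p_assoa.positions)
        assert np.array_equal(p_ss.fitness, p_assoa.fitness)

    def test_sphere_convergence(self, box10):
        result = run_optimizer("assoa", box10, "sphere", ASSOAParams(n=30, t_m=200), seed=1)
        assert result.best_fitness < 1e-2
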