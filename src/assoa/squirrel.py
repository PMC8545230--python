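"""Squirrel-search update rules: the basic three gliding cases (SS) and the
advanced variant (ASSOA) adding diagonal, vertical/horizontal and exponential
movements plus a reshaped seasonal relocation.

Movement cases, per iteration:

* case 1 — acorn agents glide toward the hickory tree (or relocate randomly
  with predator probability P_dp);
* case 2 — one random half of the normal agents glides toward a random acorn
  tree (or relocates randomly);
* case 3 — the other half glides toward the hickory tree (or relocates
  randomly);
* case 4 (ASSOA, p < 0.5, P_a < a) — normals move diagonally:
  x + v + c1 r (hickory - x) + c2 r (nearest acorn - x);
* case 5 (ASSOA, P_d < d) — vertical move toward a random normal agent when it
  is fitter, else horizontal move toward the hickory, each with the velocity
  term;
* case 6 (ASSOA, otherwise) — exponential move
  x + |x_rand - x| exp(b tau) cos(2 pi tau) with tau = t / t_m.

Seasonal monitoring: when every acorn agent has drifted within S_min of the
hickory, the normal agents are relocated — by a Lévy flight over the box in
SS, and by the hickory-anchored relocation equation in ASSOA.

The velocity matrix is initialized to zero and — exactly as in the algorithm
listing, which states no update equation — never modified by the steps; the
velocity terms in cases 4-5 therefore vanish unless the caller seeds nonzero
velocities.  (Treating velocity as the previous displacement was tried and
measurably degrades convergence by feeding relocation jumps back into the
moves.)
"""

from __future__ import annotations

import math

import numpy as np

from .core import (
    assign_roles,
    evaluate_population,
    levy_sample,
    register_algorithm,
    seasonal_constant,
    seasonal_minimum,
)
from .errors import ConfigurationError
from .space import ASSOAParams, Population, RoleAssignment, SearchSpace, SSParams, as_rng

# MoveTrace case labels
CASE_GLIDE_ACORN = "case1-glide"
CASE_GLIDE_N2 = "case2-glide"
CASE_GLIDE_N3 = "case3-glide"
CASE_RANDOM = "random-location"
CASE_DIAGONAL = "case4-diagonal"
CASE_VERTICAL = "case5-vertical"
CASE_HORIZONTAL = "case5-horizontal"
CASE_EXPONENTIAL = "case6-exponential"
CASE_RELOCATE_SS = "relocation-ss"
CASE_RELOCATE_ASSOA = "relocation-assoa"

BASIC_CASES = frozenset(
    {CASE_GLIDE_ACORN, CASE_GLIDE_N2, CASE_GLIDE_N3, CASE_RANDOM}
)


def glide_move(x: np.ndarray, target: np.ndarray, d_g: float, G_c: float) -> np.ndarray:
    """One gliding step x + d_g * G_c * (target - x)."""
    x = np.asarray(x, dtype=float)
    target = np.asarray(target, dtype=float)
    if x.shape != target.shape:
        raise ConfigurationError(f"glide dimension mismatch: {x.shape} vs {target.shape}")
    return x + d_g * G_c * (target - x)


def relocate_assoa(x_nt: np.ndarray, x_ht: np.ndarray, r: float, eps: float = 1e-10) -> np.ndarray:
    """ASSOA seasonal relocation, component-wise:

    x_ht + 2 r ((x_ht - x_nt)(1 - ((x_ht + x_nt) / x_nt)^2))

    A zero component in the denominator is replaced by +eps (sign(0) = +1) so
    symmetric boxes never divide by zero.  A normal agent already at the
    hickory stays there (the leading factor vanishes).
    """
    x_nt = np.asarray(x_nt, dtype=float)
    x_ht = np.asarray(x_ht, dtype=float)
    if x_nt.shape != x_ht.shape:
        raise ConfigurationError(f"relocation dimension mismatch: {x_nt.shape} vs {x_ht.shape}")
    denom = np.where(x_nt == 0.0, eps, x_nt)
    return x_ht + 2.0 * r * ((x_ht - x_nt) * (1.0 - ((x_ht + x_nt) / denom) ** 2))


def _record(trace, t, agent, case):
    if trace is not None:
        trace.append((t, int(agent), case))


def _apply_glide_cases(new_pos, pop, roles, params, space, t, rng, trace):
    """Cases 1-3, shared verbatim between SS and the p >= 0.5 branch of ASSOA.

    The random-draw order per agent is fixed (gate draw, then target/acorn
    index, then gliding distance or random location) so the two algorithms
    consume identical rng streams on this branch.
    """
    src = pop.positions
    ht = src[roles.hickory]
    for i in roles.acorn:
        if rng.uniform() >= params.P_dp:
            d_g = rng.uniform(params.dg_low, params.dg_high)
            new_pos[i] = glide_move(src[i], ht, d_g, params.G_c)
            _record(trace, t, i, CASE_GLIDE_ACORN)
        else:
            new_pos[i] = space.sample_uniform(rng)
            _record(trace, t, i, CASE_RANDOM)
    for i in roles.n2_split:
        if rng.uniform() >= params.P_dp:
            acorn_idx = roles.acorn[rng.integers(3)]
            d_g = rng.uniform(params.dg_low, params.dg_high)
            new_pos[i] = glide_move(src[i], src[acorn_idx], d_g, params.G_c)
            _record(trace, t, i, CASE_GLIDE_N2)
        else:
            new_pos[i] = space.sample_uniform(rng)
            _record(trace, t, i, CASE_RANDOM)
    for i in roles.n3_split:
        if rng.uniform() >= params.P_dp:
            d_g = rng.uniform(params.dg_low, params.dg_high)
            new_pos[i] = glide_move(src[i], src[roles.hickory], d_g, params.G_c)
            _record(trace, t, i, CASE_GLIDE_N3)
        else:
            new_pos[i] = space.sample_uniform(rng)
            _record(trace, t, i, CASE_RANDOM)


def _finish_step(pop, new_pos, space, objective):
    new_pos = space.clip(new_pos)
    pop.positions = new_pos
    pop.fitness[:] = np.nan
    evaluate_population(pop, objective)
    return pop


def _seasonal_triggered(new_pos, roles, t, t_m):
    diff = new_pos[roles.acorn] - new_pos[roles.hickory]
    s_c = np.sqrt(np.sum(diff**2, axis=1))
    return float(s_c.min()) < seasonal_minimum(t, t_m)


def ss_step(
    pop: Population,
    roles: RoleAssignment,
    params: SSParams,
    space: SearchSpace,
    objective,
    t: int,
    rng,
    trace: list | None = None,
) -> Population:
    """One iteration of the basic squirrel-search update."""
    rng = as_rng(rng)
    new_pos = pop.positions.copy()
    _apply_glide_cases(new_pos, pop, roles, params, space, t, rng, trace)
    if _seasonal_triggered(new_pos, roles, t, params.t_m):
        span = space.upper - space.lower
        for i in roles.normal:
            step = levy_sample(params.beta, space.dims, rng)
            new_pos[i] = space.lower + step * span
            _record(trace, t, i, CASE_RELOCATE_SS)
    return _finish_step(pop, new_pos, space, objective)


def assoa_step(
    pop: Population,
    roles: RoleAssignment,
    params: ASSOAParams,
    space: SearchSpace,
    objective,
    t: int,
    rng,
    trace: list | None = None,
) -> Population:
    """One iteration of the advanced squirrel-search update."""
    rng = as_rng(rng)
    new_pos = pop.positions.copy()
    src = pop.positions
    fitness = pop.checked_fitness()

    p = params.p_pin if params.p_pin is not None else rng.uniform()
    if p >= params.p_threshold:
        _apply_glide_cases(new_pos, pop, roles, params, space, t, rng, trace)
    else:
        P_a = rng.uniform()
        a = params.a_pin if params.a_pin is not None else rng.uniform()
        ht = src[roles.hickory]
        if P_a < a:
            # case 4: diagonal move toward hickory + nearest acorn
            acorn_pos = src[roles.acorn]
            for i in roles.normal:
                dist = np.sum((acorn_pos - src[i]) ** 2, axis=1)
                nearest = src[roles.acorn[int(np.argmin(dist))]]
                c1 = rng.uniform()
                c2 = rng.uniform()
                r = rng.uniform()
                new_pos[i] = (
                    src[i]
                    + pop.velocities[i]
                    + c1 * r * (ht - src[i])
                    + c2 * r * (nearest - src[i])
                )
                _record(trace, t, i, CASE_DIAGONAL)
        else:
            rand_agent = roles.normal[rng.integers(roles.normal.size)]
            P_d = rng.uniform()
            d_threshold = params.d_pin if params.d_pin is not None else rng.uniform()
            if P_d < d_threshold:
                # case 5: vertical toward the random agent when it is fitter,
                # else horizontal toward the hickory
                f_rand = fitness[rand_agent]
                for i in roles.normal:
                    c = rng.uniform()
                    r = rng.uniform()
                    if f_rand < fitness[i]:
                        new_pos[i] = src[i] + pop.velocities[i] + c * r * (src[rand_agent] - src[i])
                        _record(trace, t, i, CASE_VERTICAL)
                    else:
                        new_pos[i] = src[i] + pop.velocities[i] + c * r * (ht - src[i])
                        _record(trace, t, i, CASE_HORIZONTAL)
            else:
                # case 6: exponential move, normalized iteration tau = t / t_m
                tau = t / params.t_m
                envelope = math.cos(2.0 * math.pi * tau)
                for i in roles.normal:
                    b = rng.uniform(params.b_range[0], params.b_range[1])
                    new_pos[i] = src[i] + np.abs(src[rand_agent] - src[i]) * math.exp(b * tau) * envelope
                    _record(trace, t, i, CASE_EXPONENTIAL)

    if _seasonal_triggered(new_pos, roles, t, params.t_m):
        ht_pos = new_pos[roles.hickory]
        for i in roles.normal:
            r = rng.uniform()
            new_pos[i] = relocate_assoa(new_pos[i], ht_pos, r)
            _record(trace, t, i, CASE_RELOCATE_ASSOA)
    return _finish_step(pop, new_pos, space, objective)


# ---------------------------------------------------------------------------
# harness drivers

def _ss_driver(pop, params, space, objective, t, rng, trace):
    roles = assign_roles(pop, rng)
    ss_step(pop, roles, params, space, objective, t, rng, trace)


def _assoa_driver(pop, params, space, objective, t, rng, trace):
    roles = assign_roles(pop, rng)
    assoa_step(pop, roles, params, space, objective, t, rng, trace)


register_algorithm("ss", _ss_driver)
register_algorithm("assoa", _assoa_driver)
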