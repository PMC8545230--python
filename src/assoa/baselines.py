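"""Comparison baselines: canonical Grey Wolf Optimizer and a real-coded
generational Genetic Algorithm.

Both plug into the shared run harness (box bounds, seeded determinism,
best-so-far curves) so the squirrel-search variants can be compared against
them on identical objectives and paired seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import evaluate_population, register_algorithm
from .errors import ConfigurationError
from .space import Population, SearchSpace, as_rng


@dataclass
class GWOParams:
    """Grey wolf settings; the a-coefficient decays linearly 2 -> 0."""

    n: int = 30
    t_m: int = 100
    a_start: float = 2.0
    a_end: float = 0.0

    def __post_init__(self):
        if self.t_m < 1:
            raise ConfigurationError("t_m must be >= 1")
        if self.n < 3:
            raise ConfigurationError("GWO needs at least 3 agents (alpha, beta, delta)")


@dataclass
class GAParams:
    """Generational GA: tournament selection, arithmetic crossover,
    per-gene uniform mutation, elitism."""

    n: int = 30
    t_m: int = 100
    crossover_prob: float = 0.9
    mutation_prob: float | None = None   # default 1/d, resolved at step time
    tournament_size: int = 3
    elitism: int = 1

    def __post_init__(self):
        if self.t_m < 1:
            raise ConfigurationError("t_m must be >= 1")
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ConfigurationError("crossover_prob must lie in [0, 1]")
        if self.mutation_prob is not None and not 0.0 <= self.mutation_prob <= 1.0:
            raise ConfigurationError("mutation_prob must lie in [0, 1]")
        if self.elitism >= self.n:
            raise ConfigurationError("elitism count must be smaller than the population size")


def gwo_step(
    pop: Population,
    params: GWOParams,
    space: SearchSpace,
    objective,
    t: int,
    rng,
    a_override: float | None = None,
) -> Population:
    """Canonical GWO update: each agent moves to the mean of three
    leader-guided candidates built from the alpha/beta/delta wolves."""
    rng = as_rng(rng)
    fitness = pop.checked_fitness()
    order = np.argsort(fitness, kind="stable")
    leaders = pop.positions[order[:3]]
    if a_override is not None:
        a = a_override
    else:
        frac = t / params.t_m
        a = params.a_start + (params.a_end - params.a_start) * frac
    d = space.dims
    new_pos = np.empty_like(pop.positions)
    for i in range(pop.n):
        candidate = np.zeros(d)
        for leader in leaders:
            r1 = rng.uniform(size=d)
            r2 = rng.uniform(size=d)
            A = 2.0 * a * r1 - a
            C = 2.0 * r2
            candidate += leader - A * np.abs(C * leader - pop.positions[i])
        new_pos[i] = candidate / 3.0
    new_pos = space.clip(new_pos)
    pop.velocities = new_pos - pop.positions
    pop.positions = new_pos
    pop.fitness[:] = np.nan
    evaluate_population(pop, objective)
    return pop


def ga_step(
    pop: Population,
    params: GAParams,
    space: SearchSpace,
    objective,
    t: int,
    rng,
) -> Population:
    """One GA generation: elites pass unchanged, the rest are bred by
    tournament selection + arithmetic crossover + uniform mutation."""
    rng = as_rng(rng)
    fitness = pop.checked_fitness()
    order = np.argsort(fitness, kind="stable")
    d = space.dims
    pm = params.mutation_prob if params.mutation_prob is not None else 1.0 / d

    new_pos = np.empty_like(pop.positions)
    elites = order[: params.elitism]
    new_pos[: params.elitism] = pop.positions[elites]

    def tournament() -> np.ndarray:
        contenders = rng.integers(0, pop.n, size=params.tournament_size)
        winner = contenders[np.argmin(fitness[contenders])]
        return pop.positions[winner]

    for slot in range(params.elitism, pop.n):
        p1 = tournament()
        p2 = tournament()
        if rng.uniform() < params.crossover_prob:
            u = rng.uniform(size=d)
            child = u * p1 + (1.0 - u) * p2
        else:
            child = p1.copy()
        mutate = rng.uniform(size=d) < pm
        if mutate.any():
            child = child.copy()
            child[mutate] = rng.uniform(space.lower[mutate], space.upper[mutate])
        new_pos[slot] = child

    new_pos = space.clip(new_pos)
    pop.velocities = new_pos - pop.positions
    pop.positions = new_pos
    pop.fitness[:] = np.nan
    evaluate_population(pop, objective)
    return pop


def _gwo_driver(pop, params, space, objective, t, rng, trace):
    gwo_step(pop, params, space, objective, t, rng)


def _ga_driver(pop, params, space, objective, t, rng, trace):
    ga_step(pop, params, space, objective, t, rng)


register_algorithm("gwo", _gwo_driver)
register_algorithm("ga", _ga_driver)
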