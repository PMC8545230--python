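"""Population machinery: initialization, evaluation, roles, Lévy flights,
seasonal monitoring, built-in objectives and the generic run harness."""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
from scipy.special import gamma as _gamma

from .errors import ConfigurationError, EvaluationError, UnknownAlgorithmError
from .space import (
    ASSOAParams,
    OptimizerResult,
    Population,
    RoleAssignment,
    SearchSpace,
    SSParams,
    as_rng,
)

# ---------------------------------------------------------------------------
# objectives

def sphere(x: np.ndarray) -> float:
    return float(np.sum(np.asarray(x) ** 2))


def rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x)
    return float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


def rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


OBJECTIVES: dict[str, Callable[[np.ndarray], float]] = {
    "sphere": sphere,
    "rastrigin": rastrigin,
    "rosenbrock": rosenbrock,
}


def get_objective(objective) -> Callable[[np.ndarray], float]:
    """Resolve a named built-in or pass a user callable through."""
    if callable(objective):
        return objective
    try:
        return OBJECTIVES[objective]
    except KeyError:
        raise UnknownAlgorithmError(
            f"unknown objective {objective!r}; built-ins: {sorted(OBJECTIVES)}"
        ) from None


class CountingObjective:
    """Wrap an objective with an evaluation counter and optional negation."""

    def __init__(self, fn: Callable[[np.ndarray], float], negate: bool = False):
        self._fn = fn
        self._negate = negate
        self.evaluations = 0

    def __call__(self, x: np.ndarray) -> float:
        self.evaluations += 1
        value = float(self._fn(x))
        return -value if self._negate else value


# ---------------------------------------------------------------------------
# population operations

def init_population(space: SearchSpace, n: int, seed) -> Population:
    """Uniform initial positions in the box, zero velocities, unset fitness."""
    if n < 5:
        raise ConfigurationError(
            f"population size {n} < 5: need 1 hickory + 3 acorn + >=1 normal agent"
        )
    rng = as_rng(seed)
    positions = space.sample_uniform(rng, n)
    return Population(
        positions=positions,
        velocities=np.zeros_like(positions),
        fitness=np.full(n, np.nan),
    )


def evaluate_population(pop: Population, objective) -> Population:
    """Evaluate the objective at every position, in agent order."""
    for i in range(pop.n):
        value = float(objective(pop.positions[i]))
        if not math.isfinite(value):
            raise EvaluationError(f"objective returned non-finite value {value!r} for agent {i}")
        pop.fitness[i] = value
    return pop


def assign_roles(pop: Population, rng) -> RoleAssignment:
    """Sort agents by fitness (stable; lower index wins ties) and partition.

    The normal agents are split uniformly at random each iteration into the
    acorn-bound group (n2) and the hickory-bound group (n3).
    """
    if pop.n < 5:
        raise ConfigurationError("role assignment needs at least 5 agents")
    rng = as_rng(rng)
    order = np.argsort(pop.checked_fitness(), kind="stable")
    hickory = int(order[0])
    acorn = order[1:4].copy()
    normal = order[4:].copy()
    to_acorn = rng.uniform(size=normal.size) < 0.5
    return RoleAssignment(
        hickory=hickory,
        acorn=acorn,
        normal=normal,
        n2_split=normal[to_acorn],
        n3_split=normal[~to_acorn],
    )


# ---------------------------------------------------------------------------
# Lévy flight

def levy_sigma(beta: float) -> float:
    """Scale factor of the Lévy step distribution.

    sigma = (Gamma(1+b) sin(pi b/2) / (Gamma((1+b)/2) b 2^((b-1)/2)))^(1/b)
    """
    if not 0.0 < beta <= 2.0:
        raise ConfigurationError(f"Levy exponent beta={beta} outside (0, 2]")
    num = _gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = _gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return float((num / den) ** (1.0 / beta))


def levy_sample(beta: float, dims: int, rng) -> np.ndarray:
    """Heavy-tailed Lévy step: 0.01 * r_a * sigma / |r_b|^(1/beta) per dimension.

    r_a and r_b are uniform(0,1) draws; a zero r_b is redrawn so the ratio is
    always finite.
    """
    sigma = levy_sigma(beta)
    rng = as_rng(rng)
    out = np.empty(dims)
    for j in range(dims):
        r_a = rng.uniform()
        r_b = rng.uniform()
        while r_b == 0.0:
            r_b = rng.uniform()
        out[j] = 0.01 * r_a * sigma / abs(r_b) ** (1.0 / beta)
    return out


# ---------------------------------------------------------------------------
# seasonal monitoring

def seasonal_constant(pop: Population, roles: RoleAssignment) -> np.ndarray:
    """Euclidean distance from each acorn agent to the hickory agent."""
    diff = pop.positions[roles.acorn] - pop.positions[roles.hickory]
    return np.sqrt(np.sum(diff**2, axis=1))


def seasonal_minimum(t: int, t_m: int) -> float:
    """Decaying trigger threshold 1e-6 / 365^(2.5 t / t_m)."""
    if t_m == 0:
        raise ConfigurationError("t_m must be positive")
    return 1e-6 / 365.0 ** (2.5 * t / t_m)


# ---------------------------------------------------------------------------
# run harness

# Registered per-iteration step drivers.  Each driver advances the population
# by one full iteration (roles, moves, seasonal check, re-evaluation) and has
# signature (pop, params, space, objective, t, rng, trace).
_REGISTRY: dict[str, Callable] = {}


def register_algorithm(name: str, driver: Callable) -> None:
    _REGISTRY[name] = driver


def registered_algorithms() -> list[str]:
    _ensure_registered()
    return sorted(_REGISTRY)


def _ensure_registered() -> None:
    if not _REGISTRY:
        from . import baselines, squirrel  # noqa: F401  (registration side effect)


def run_optimizer(
    algorithm: str,
    space: SearchSpace,
    objective,
    params,
    seed: int,
    record_trace: bool = False,
    maximize: bool = False,
) -> OptimizerResult:
    """Run a registered optimizer for params.t_m iterations.

    Deterministic given (algorithm, space, objective, params, seed): one
    Generator stream, seeded here, drives initialization and every iteration.
    The best-so-far curve is recorded after each iteration and is therefore
    non-increasing by construction.
    """
    _ensure_registered()
    if algorithm not in _REGISTRY:
        raise UnknownAlgorithmError(
            f"unknown algorithm {algorithm!r}; registered: {sorted(_REGISTRY)}"
        )
    driver = _REGISTRY[algorithm]
    rng = np.random.default_rng(seed)
    counting = CountingObjective(get_objective(objective), negate=maximize)
    pop = init_population(space, params.n, rng)
    evaluate_population(pop, counting)

    trace: list | None = [] if record_trace else None
    best = pop.best_index()
    best_fitness = float(pop.fitness[best])
    best_position = pop.positions[best].copy()
    curve = np.empty(params.t_m)
    for t in range(1, params.t_m + 1):
        driver(pop, params, space, counting, t, rng, trace)
        i = pop.best_index()
        if pop.fitness[i] < best_fitness:
            best_fitness = float(pop.fitness[i])
            best_position = pop.positions[i].copy()
        curve[t - 1] = best_fitness

    if maximize:
        best_fitness = -best_fitness
        curve = -curve
    return OptimizerResult(
        algorithm=algorithm,
        best_position=best_position,
        best_fitness=best_fitness,
        curve=curve,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        evaluations=counting.evaluations,
        trace=trace,
    )
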