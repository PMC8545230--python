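"""Search-space and population containers shared by every optimizer.

The population model follows the flying-squirrel metaphor: ``n`` agents occupy
positions in a box-bounded ``d``-dimensional space; after each fitness sort the
single best agent sits on the *hickory* tree, the next three best on *acorn*
trees, and the remainder on *normal* trees.  All optimizers in this package
minimize; maximization is handled by negation at the run-harness boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, StaleFitnessError

RngLike = "int | np.random.Generator"


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed into a Generator; pass Generator-like objects
    (anything with a ``uniform`` method, e.g. scripted test doubles) through."""
    if hasattr(seed, "uniform"):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box ``[lower, upper]^d``.

    ``mode`` distinguishes plain continuous search from the binary wrapper
    layer, where continuous positions in ``[0, 1]^d`` are thresholded into
    feature masks by a sigmoid transfer function.
    """

    dims: int
    lower: np.ndarray
    upper: np.ndarray
    mode: str = "continuous"

    def __post_init__(self):
        if self.dims < 1:
            raise ConfigurationError("dims must be >= 1")
        lower = np.broadcast_to(np.asarray(self.lower, dtype=float), (self.dims,)).copy()
        upper = np.broadcast_to(np.asarray(self.upper, dtype=float), (self.dims,)).copy()
        if not np.all(lower < upper):
            raise ConfigurationError("lower bound must be strictly below upper bound in every dimension")
        if self.mode not in ("continuous", "binary-from-continuous"):
            raise ConfigurationError(f"unknown space mode {self.mode!r}")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @classmethod
    def box(cls, dims: int, lower: float, upper: float, mode: str = "continuous") -> "SearchSpace":
        return cls(dims=dims, lower=np.full(dims, float(lower)), upper=np.full(dims, float(upper)), mode=mode)

    @classmethod
    def unit(cls, dims: int, mode: str = "continuous") -> "SearchSpace":
        return cls.box(dims, 0.0, 1.0, mode=mode)

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def sample_uniform(self, rng: np.random.Generator, n: int | None = None) -> np.ndarray:
        if n is None:
            return rng.uniform(self.lower, self.upper)
        return rng.uniform(self.lower, self.upper, size=(n, self.dims))


@dataclass
class Population:
    """Positions, velocities and fitness of ``n`` agents.

    Fitness entries are NaN sentinels until :func:`evaluate_population` runs;
    any read through :meth:`checked_fitness` of a stale vector raises.
    """

    positions: np.ndarray
    velocities: np.ndarray
    fitness: np.ndarray

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def dims(self) -> int:
        return self.positions.shape[1]

    def checked_fitness(self) -> np.ndarray:
        if np.isnan(self.fitness).any():
            raise StaleFitnessError(
                "population fitness contains unevaluated entries; call evaluate_population first"
            )
        return self.fitness

    def best_index(self) -> int:
        return int(np.argmin(self.checked_fitness()))

    def copy(self) -> "Population":
        return Population(self.positions.copy(), self.velocities.copy(), self.fitness.copy())


@dataclass(frozen=True)
class RoleAssignment:
    """Hickory / acorn / normal partition of agent indices by sorted fitness.

    ``n2_split`` and ``n3_split`` are the random partition of the normal agents
    into the group gliding toward an acorn tree and the group gliding toward
    the hickory tree this iteration.
    """

    hickory: int
    acorn: np.ndarray       # 3 indices, ranks 2..4
    normal: np.ndarray      # remaining n-4 indices
    n2_split: np.ndarray
    n3_split: np.ndarray


@dataclass
class SSParams:
    """Parameters of the basic squirrel-search algorithm.

    G_c is the gliding constant (1.9), P_dp the predator-presence probability
    (0.1) under which a gliding agent abandons its glide for a uniform random
    location, beta the Lévy exponent (1.5), and (dg_low, dg_high) the sampling
    range of the random gliding distance d_g.
    """

    n: int = 30
    t_m: int = 100
    G_c: float = 1.9
    P_dp: float = 0.1
    beta: float = 1.5
    dg_low: float = 0.5
    dg_high: float = 1.11

    def __post_init__(self):
        if not 0.0 < self.P_dp < 1.0:
            raise ConfigurationError("P_dp must lie strictly inside (0, 1)")
        if self.dg_low > self.dg_high:
            raise ConfigurationError("dg_low must not exceed dg_high")
        if self.t_m < 1:
            raise ConfigurationError("t_m must be >= 1")
        if self.n < 5:
            raise ConfigurationError(
                f"population size {self.n} < 5: need 1 hickory + 3 acorn + >=1 normal agent"
            )


@dataclass
class ASSOAParams(SSParams):
    """Parameters of the advanced squirrel-search algorithm.

    On each iteration a single uniform draw p gates the move family: p >=
    p_threshold runs the three basic gliding cases; otherwise the added
    diagonal / vertical-horizontal / exponential moves fire for the normal
    agents.  p, P_a, a, P_d and d_threshold are drawn uniform(0,1) per
    iteration unless pinned here (pinning exists for deterministic branch
    tests and for forcing the degenerate-to-SS regime).
    """

    p_threshold: float = 0.5
    b_range: tuple = (0.0, 1.0)
    p_pin: float | None = None
    a_pin: float | None = None
    d_pin: float | None = None

    def __post_init__(self):
        super().__post_init__()
        if not 0.0 <= self.p_threshold <= 1.0:
            raise ConfigurationError("p_threshold must lie in [0, 1]")


@dataclass
class OptimizerResult:
    """Outcome of one optimizer run: the incumbent and its history."""

    algorithm: str
    best_position: np.ndarray
    best_fitness: float
    curve: np.ndarray           # best-so-far fitness per iteration (non-increasing)
    seed: int | None
    evaluations: int
    trace: "list | None" = field(default=None, repr=False)

    def curve_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"iteration": np.arange(1, len(self.curve) + 1), "best_fitness": self.curve}
        )
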