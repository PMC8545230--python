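"""Binary wrapper feature selection.

A continuous position in [0, 1]^D is thresholded into a feature mask by a
steep sigmoid transfer function; the mask is scored by the misclassification
rate of a wrapper classifier (k-nearest-neighbours by default) trained on the
train split and evaluated on the validation split, combined with the selected
fraction of features:

    F = h1 * Err + h2 * |selected| / D,   h2 = 1 - h1,  h1 = 0.99 by default

so classification error dominates and subset size breaks near-ties.  The
module also ships an exhaustive-enumeration oracle for small D used to verify
that the metaheuristics find the true global minimum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.neighbors import KNeighborsClassifier

from .core import run_optimizer
from .datasets import FeatureDataset
from .errors import ConfigurationError
from .space import ASSOAParams, OptimizerResult, SearchSpace


@dataclass(frozen=True)
class FSConfig:
    """Wrapper-selection settings.

    ``h1`` weights classification error against selected-subset size
    (``h2 = 1 - h1`` always).  ``classifier`` is the error oracle inside the
    fitness: "knn" (default) or "mlp".  ``empty_mask_policy`` decides what an
    all-zero mask scores: "worst" assigns error 1.0 (ratio 0), never a crash.
    """

    h1: float = 0.99
    classifier: str = "knn"
    knn_k: int = 5
    empty_mask_policy: str = "worst"
    mlp_hidden: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.h1 <= 1.0:
            raise ConfigurationError("h1 must lie in [0, 1]")
        if self.classifier not in ("knn", "mlp"):
            raise ConfigurationError(f"unknown wrapper classifier {self.classifier!r}")
        if self.empty_mask_policy not in ("worst", "random-feature"):
            raise ConfigurationError(f"unknown empty-mask policy {self.empty_mask_policy!r}")

    @property
    def h2(self) -> float:
        return 1.0 - self.h1


@dataclass(frozen=True)
class SubsetEvaluation:
    """A feature mask with its wrapper error, selected fraction and fitness."""

    mask: np.ndarray
    err: float
    ratio: float
    fitness: float


def binarize(x: np.ndarray) -> np.ndarray:
    """Sigmoid transfer: component j selected iff 1/(1+exp(-10(x_j-0.5))) >= 0.5,
    which reduces to x_j >= 0.5."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ConfigurationError("binarize requires finite entries")
    sig = 1.0 / (1.0 + np.exp(-10.0 * (x - 0.5)))
    return (sig >= 0.5).astype(np.int8)


def fs_fitness(err: float, mask: np.ndarray, h1: float) -> float:
    """Weighted sum of error rate and selected-feature fraction."""
    if not 0.0 <= h1 <= 1.0:
        raise ConfigurationError("h1 must lie in [0, 1]")
    mask = np.asarray(mask)
    ratio = float(np.count_nonzero(mask)) / mask.size
    return h1 * float(err) + (1.0 - h1) * ratio


def subset_error(data: FeatureDataset, mask: np.ndarray, cfg: FSConfig, seed=0) -> float:
    """Validation-split misclassification rate of the wrapper classifier
    trained on the train split restricted to the selected columns."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size != data.n_features:
        raise ConfigurationError(
            f"mask length {mask.size} does not match feature count {data.n_features}"
        )
    if not mask.any():
        if cfg.empty_mask_policy == "worst":
            return 1.0
        rng = np.random.default_rng(seed)
        forced = np.zeros_like(mask)
        forced[rng.integers(mask.size)] = True
        mask = forced

    X_train = data.X[data.train_idx][:, mask]
    X_val = data.X[data.val_idx][:, mask]
    y_train = data.y[data.train_idx]
    y_val = data.y[data.val_idx]

    if cfg.classifier == "knn":
        k = min(cfg.knn_k, len(y_train))
        clf = KNeighborsClassifier(n_neighbors=k)
        clf.fit(X_train, y_train)
        pred = clf.predict(X_val)
        return float(np.mean(pred != y_val))

    # "mlp": a short metaheuristic-trained perceptron mirroring the final
    # classification stage; markedly slower than knn, kept for parity studies.
    from .mlp import train_mlp_with_optimizer

    sub = data.subset_features(mask)
    result = train_mlp_with_optimizer(
        sub,
        algorithm="assoa",
        params=ASSOAParams(n=10, t_m=20),
        hidden=cfg.mlp_hidden,
        seed=seed,
    )
    pred = result.model.predict(sub.X[sub.val_idx])
    return float(np.mean(pred != sub.y[sub.val_idx]))


class FSObjective:
    """Continuous objective over [0,1]^D evaluating masks through a cache.

    The objective value depends on the position only through its binarized
    mask, so repeated masks hit the cache; ``n_error_evals`` counts distinct
    wrapper-classifier fits.
    """

    def __init__(self, data: FeatureDataset, cfg: FSConfig, seed=0):
        self.data = data
        self.cfg = cfg
        self.seed = seed
        self._cache: dict[bytes, SubsetEvaluation] = {}
        self.n_error_evals = 0

    def evaluate_mask(self, mask: np.ndarray) -> SubsetEvaluation:
        mask = np.asarray(mask, dtype=np.int8)
        key = mask.tobytes()
        hit = self._cache.get(key)
        if hit is None:
            err = subset_error(self.data, mask, self.cfg, self.seed)
            self.n_error_evals += 1
            ratio = float(np.count_nonzero(mask)) / mask.size
            hit = SubsetEvaluation(
                mask=mask.copy(), err=err, ratio=ratio, fitness=fs_fitness(err, mask, self.cfg.h1)
            )
            self._cache[key] = hit
        return hit

    def __call__(self, x: np.ndarray) -> float:
        return self.evaluate_mask(binarize(x)).fitness


def make_fs_objective(data: FeatureDataset, cfg: FSConfig | None = None, seed=0) -> FSObjective:
    return FSObjective(data, cfg or FSConfig(), seed)


def exhaustive_best_subset(data: FeatureDataset, cfg: FSConfig | None = None, seed=0) -> SubsetEvaluation:
    """Enumerate every non-empty mask (plus the empty-mask policy value) and
    return the global fitness minimizer; ties go to the lexicographically
    smallest mask.  Guarded to D <= 20."""
    cfg = cfg or FSConfig()
    D = data.n_features
    if D > 20:
        raise ConfigurationError(
            f"exhaustive enumeration over 2^{D} masks refused (D <= 20); "
            "use a metaheuristic for larger feature counts"
        )
    objective = make_fs_objective(data, cfg, seed)
    best: SubsetEvaluation | None = None
    for bits in itertools.product((0, 1), repeat=D):
        mask = np.array(bits, dtype=np.int8)
        evaluation = objective.evaluate_mask(mask)
        if best is None or evaluation.fitness < best.fitness:
            best = evaluation
    return best


@dataclass
class SelectionResult:
    """Outcome of one metaheuristic feature-selection run."""

    best: SubsetEvaluation
    optimizer: OptimizerResult
    objective: FSObjective = field(repr=False)


def select_features(
    data: FeatureDataset,
    algorithm: str = "assoa",
    params=None,
    cfg: FSConfig | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Run a registered optimizer over [0,1]^D and binarize its best position."""
    cfg = cfg or FSConfig()
    if params is None:
        params = ASSOAParams(n=20, t_m=50)
    objective = make_fs_objective(data, cfg, seed)
    space = SearchSpace.unit(data.n_features, mode="binary-from-continuous")
    result = run_optimizer(algorithm, space, objective, params, seed)
    best = objective.evaluate_mask(binarize(result.best_position))
    return SelectionResult(best=best, optimizer=result, objective=objective)
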