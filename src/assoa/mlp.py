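"""Single-hidden-layer perceptron trained by metaheuristic weight search.

The network is deliberately minimal: sigmoid hidden units, a *linear* output
layer, and class decision by argmax over the output scores.  There is no
backpropagation anywhere — a registered optimizer searches the flat weight
vector in [-1, 1]^L, scored by misclassification rate on the validation
split.  Inputs are min-max scaled with statistics frozen from the train split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import run_optimizer
from .datasets import FeatureDataset
from .errors import ConfigurationError
from .space import ASSOAParams, OptimizerResult, SearchSpace


@dataclass(frozen=True)
class MLPArchitecture:
    n_in: int
    m_hidden: int
    n_out: int

    def __post_init__(self):
        if min(self.n_in, self.m_hidden, self.n_out) < 1:
            raise ConfigurationError("all layer sizes must be >= 1")

    @property
    def n_weights(self) -> int:
        return self.n_in * self.m_hidden + self.m_hidden + self.m_hidden * self.n_out + self.n_out

    @classmethod
    def for_dataset(cls, data: FeatureDataset, hidden: int | None = None) -> "MLPArchitecture":
        # classic hidden-width heuristic 2*n_in + 1 when unspecified
        n_in = data.n_features
        return cls(n_in, hidden if hidden is not None else 2 * n_in + 1, data.classes.size)


def encode_weights(arch: MLPArchitecture, W1, b1, W2, b2) -> np.ndarray:
    """Flatten to [W1 row-major, b1, W2 row-major, b2]."""
    flat = np.concatenate([np.ravel(W1), np.ravel(b1), np.ravel(W2), np.ravel(b2)])
    if flat.size != arch.n_weights:
        raise ConfigurationError(
            f"weight blocks give length {flat.size}, expected {arch.n_weights}"
        )
    return flat


def decode_weights(arch: MLPArchitecture, flat: np.ndarray):
    flat = np.asarray(flat, dtype=float)
    if flat.size != arch.n_weights:
        raise ConfigurationError(
            f"flat weight vector has length {flat.size}, expected {arch.n_weights}"
        )
    i, m, o = arch.n_in, arch.m_hidden, arch.n_out
    pos = 0
    W1 = flat[pos : pos + i * m].reshape(i, m); pos += i * m
    b1 = flat[pos : pos + m]; pos += m
    W2 = flat[pos : pos + m * o].reshape(m, o); pos += m * o
    b2 = flat[pos : pos + o]
    return W1, b1, W2, b2


def minmax_scale(x: np.ndarray, mins: np.ndarray, maxs: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min) per feature; constant features map to 0.

    Values outside the training range extrapolate (no re-clipping)."""
    x = np.asarray(x, dtype=float)
    mins = np.asarray(mins, dtype=float)
    maxs = np.asarray(maxs, dtype=float)
    span = maxs - mins
    if np.any(span < 0):
        raise ConfigurationError("maxs must be >= mins")
    safe = np.where(span == 0.0, 1.0, span)
    out = (x - mins) / safe
    return np.where(span == 0.0, 0.0, out)


def forward_scores(arch: MLPArchitecture, flat_weights: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Hidden sigmoid layer then linear output scores (no softmax)."""
    W1, b1, W2, b2 = decode_weights(arch, flat_weights)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != arch.n_in:
        raise ConfigurationError(f"input has {X.shape[1]} features, expected {arch.n_in}")
    S = X @ W1 + b1
    H = 1.0 / (1.0 + np.exp(-S))
    return H @ W2 + b2


@dataclass
class TrainedMLP:
    """Architecture + weights + frozen scaling statistics + label map."""

    arch: MLPArchitecture
    weights: np.ndarray
    feature_mins: np.ndarray
    feature_maxs: np.ndarray
    classes: np.ndarray

    def scores(self, X: np.ndarray) -> np.ndarray:
        Xs = minmax_scale(np.atleast_2d(X), self.feature_mins, self.feature_maxs)
        return forward_scores(self.arch, self.weights, Xs)

    def predict(self, X: np.ndarray) -> np.ndarray:
        # argmax breaks ties toward the lower class index
        return self.classes[np.argmax(self.scores(X), axis=1)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "architecture": [self.arch.n_in, self.arch.m_hidden, self.arch.n_out],
                "weights": self.weights.tolist(),
                "feature_mins": self.feature_mins.tolist(),
                "feature_maxs": self.feature_maxs.tolist(),
                "classes": np.asarray(self.classes).tolist(),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainedMLP":
        blob = json.loads(text)
        arch = MLPArchitecture(*blob["architecture"])
        return cls(
            arch=arch,
            weights=np.asarray(blob["weights"], dtype=float),
            feature_mins=np.asarray(blob["feature_mins"], dtype=float),
            feature_maxs=np.asarray(blob["feature_maxs"], dtype=float),
            classes=np.asarray(blob["classes"]),
        )


def make_mlp_objective(data: FeatureDataset, arch: MLPArchitecture, seed=0):
    """Objective(w) = validation-split misclassification rate of the decoded
    network, with inputs scaled by train-split min/max statistics."""
    if arch.n_in != data.n_features:
        raise ConfigurationError(
            f"architecture expects {arch.n_in} inputs, dataset has {data.n_features}"
        )
    X_train = data.X[data.train_idx]
    mins = X_train.min(axis=0)
    maxs = X_train.max(axis=0)
    classes = data.classes
    class_index = {c: i for i, c in enumerate(classes)}
    X_val = minmax_scale(data.X[data.val_idx], mins, maxs)
    y_val = np.array([class_index[c] for c in data.y[data.val_idx]])

    def objective(w: np.ndarray) -> float:
        scores = forward_scores(arch, w, X_val)
        pred = np.argmax(scores, axis=1)
        return float(np.mean(pred != y_val))

    objective.scaling = (mins, maxs)  # type: ignore[attr-defined]
    objective.classes = classes       # type: ignore[attr-defined]
    return objective


def make_surrogate_objective(data: FeatureDataset, arch: MLPArchitecture, scale: float = 4.0):
    """Smooth search fitness: softmax cross-entropy at temperature ``scale``
    over the pooled train+validation samples.

    Plain misclassification rate is piecewise constant, so a derivative-free
    population search stalls on its plateaus and zero error on a small
    validation split carries no margin information.  The tempered
    cross-entropy decreases continuously as score margins grow, which steers
    the same optimizers to solutions that also classify held-out data well.
    The test split is never touched.
    """
    if arch.n_in != data.n_features:
        raise ConfigurationError(
            f"architecture expects {arch.n_in} inputs, dataset has {data.n_features}"
        )
    X_train = data.X[data.train_idx]
    mins = X_train.min(axis=0)
    maxs = X_train.max(axis=0)
    classes = data.classes
    class_index = {c: i for i, c in enumerate(classes)}
    pool = np.concatenate([data.train_idx, data.val_idx])
    X_pool = minmax_scale(data.X[pool], mins, maxs)
    y_pool = np.array([class_index[c] for c in data.y[pool]])
    rows = np.arange(y_pool.size)

    def objective(w: np.ndarray) -> float:
        scores = scale * forward_scores(arch, w, X_pool)
        scores -= scores.max(axis=1, keepdims=True)
        log_z = np.log(np.sum(np.exp(scores), axis=1))
        return float(np.mean(log_z - scores[rows, y_pool]))

    objective.scaling = (mins, maxs)  # type: ignore[attr-defined]
    objective.classes = classes       # type: ignore[attr-defined]
    return objective


@dataclass
class MLPTrainResult:
    model: TrainedMLP
    optimizer: OptimizerResult
    test_accuracy: float
    test_predictions: np.ndarray = field(repr=False)


def train_mlp_with_optimizer(
    data: FeatureDataset,
    arch: MLPArchitecture | None = None,
    algorithm: str = "assoa",
    params=None,
    seed: int = 0,
    hidden: int | None = None,
    loss: str = "cross-entropy",
) -> MLPTrainResult:
    """Search connection weights in [-1, 1]^L with a registered optimizer.

    ``loss`` picks the search fitness: "cross-entropy" (default; smooth
    tempered surrogate over train+validation, see
    :func:`make_surrogate_objective`) or "error" (raw validation
    misclassification rate).  The test split is scored once, at the end, with
    the best decoded network.
    """
    if arch is None:
        arch = MLPArchitecture.for_dataset(data, hidden)
    if params is None:
        params = ASSOAParams(n=30, t_m=100)
    if loss == "cross-entropy":
        objective = make_surrogate_objective(data, arch)
    elif loss == "error":
        objective = make_mlp_objective(data, arch, seed)
    else:
        raise ConfigurationError(f"unknown training loss {loss!r}")
    space = SearchSpace.box(arch.n_weights, -1.0, 1.0)
    result = run_optimizer(algorithm, space, objective, params, seed)
    mins, maxs = objective.scaling
    model = TrainedMLP(
        arch=arch,
        weights=result.best_position,
        feature_mins=mins,
        feature_maxs=maxs,
        classes=objective.classes,
    )
    test_pred = model.predict(data.X[data.test_idx])
    test_accuracy = float(np.mean(test_pred == data.y[data.test_idx]))
    return MLPTrainResult(
        model=model, optimizer=result, test_accuracy=test_accuracy, test_predictions=test_pred
    )
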