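"""Synthetic feature-table generators with known ground truth.

These stand in for CNN-extracted chest X-ray features so every stage of the
pipeline (wrapper selection, optimizer-trained classification, comparison
statistics) is testable without any image data.  Each generator is a pure
function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import FeatureDataset, stratified_split
from .errors import ConfigurationError
from .space import as_rng


@dataclass(frozen=True)
class PlantedSpec:
    """A feature table with a planted informative subset.

    ``k_informative`` columns carry class-separated means (adjacent class
    means ``delta`` standard deviations apart); ``redundancy`` columns are
    jittered copies of informative ones; the rest is class-independent noise.
    Columns are shuffled; the permuted ground-truth indices are recorded in
    the dataset's ``meta``.
    """

    n_samples: int = 120
    n_features: int = 10
    k_informative: int = 2
    n_classes: int = 2
    delta: float = 3.0          # class-mean separation in units of noise_sd
    noise_sd: float = 1.0
    redundancy: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.k_informative + self.redundancy > self.n_features:
            raise ConfigurationError("k_informative + redundancy must not exceed n_features")
        if self.delta < 0:
            raise ConfigurationError("delta must be non-negative")
        if self.k_informative < 1 or self.n_classes < 2:
            raise ConfigurationError("need k_informative >= 1 and n_classes >= 2")


def generate_planted(spec: PlantedSpec) -> FeatureDataset:
    rng = as_rng(spec.seed)
    n, D = spec.n_samples, spec.n_features
    # near-balanced labels, shuffled
    y = np.arange(n) % spec.n_classes
    y = y[rng.permutation(n)]

    X = np.empty((n, D))
    k = spec.k_informative
    # informative block: class-dependent means, offset so features are not
    # centred at zero (min-max scaling downstream is exercised non-trivially)
    base = 2.0
    for j in range(k):
        means = base + y * spec.delta * spec.noise_sd
        X[:, j] = rng.normal(means, spec.noise_sd)
    for j in range(k, k + spec.redundancy):
        X[:, j] = X[:, (j - k) % k] + rng.normal(0.0, 0.1 * spec.noise_sd, size=n)
    for j in range(k + spec.redundancy, D):
        X[:, j] = rng.normal(base, spec.noise_sd, size=n)

    perm = rng.permutation(D)
    X = X[:, perm]
    inv = np.argsort(perm)
    informative = np.sort(inv[:k])
    redundant = np.sort(inv[k : k + spec.redundancy])
    noise = np.sort(inv[k + spec.redundancy :])

    train, val, test = stratified_split(y, seed=rng)
    return FeatureDataset(
        X=X,
        y=y,
        feature_names=[f"f{j}" for j in range(D)],
        train_idx=train,
        val_idx=val,
        test_idx=test,
        meta={
            "informative_idx": informative,
            "redundant_idx": redundant,
            "noise_idx": noise,
            "permutation": perm,
            "spec": spec,
        },
    )


def generate_separable(
    n: int,
    d: int,
    margin: float,
    seed=0,
    label_noise: float = 0.0,
) -> FeatureDataset:
    """Two balanced classes on either side of a random hyperplane.

    Every point is placed at signed distance at least ``margin / 2`` from the
    hyperplane through the origin with unit normal ``w`` (recorded in ``meta``
    for oracle use).  ``label_noise`` flips that fraction of labels after
    placement.
    """
    if margin <= 0:
        raise ConfigurationError("margin must be positive")
    rng = as_rng(seed)
    w = rng.normal(size=d)
    w /= np.linalg.norm(w)
    y = np.arange(n) % 2
    y = y[rng.permutation(n)]
    X = rng.normal(size=(n, d))
    signed = np.where(y == 1, 1.0, -1.0)
    target = signed * (margin / 2.0 + np.abs(rng.normal(size=n)))
    X += (target - X @ w)[:, None] * w[None, :]

    y_obs = y.copy()
    if label_noise > 0.0:
        flip = rng.uniform(size=n) < label_noise
        y_obs[flip] = 1 - y_obs[flip]

    train, val, test = stratified_split(y_obs, seed=rng)
    return FeatureDataset(
        X=X,
        y=y_obs,
        feature_names=[f"f{j}" for j in range(d)],
        train_idx=train,
        val_idx=val,
        test_idx=test,
        meta={"hyperplane_w": w, "hyperplane_b": 0.0, "clean_labels": y, "margin": margin},
    )


def generate_feature_fixture(n: int, D: int = 256, seed=0) -> FeatureDataset:
    """Block-correlated non-negative features mimicking pooled CNN activations.

    Rectified Gaussian factor model: 8 blocks of correlated columns, 3
    classes, and a mild class signal planted in 5% of the columns.
    """
    rng = as_rng(seed)
    n_blocks = 8
    block_size = int(np.ceil(D / n_blocks))
    y = np.arange(n) % 3
    y = y[rng.permutation(n)]

    X = np.empty((n, D))
    for b in range(n_blocks):
        factor = rng.normal(size=n)
        for j in range(b * block_size, min((b + 1) * block_size, D)):
            loading = rng.uniform(0.6, 0.9)
            X[:, j] = loading * factor + np.sqrt(1.0 - loading**2) * rng.normal(size=n)
    signal_cols = rng.choice(D, size=max(1, D // 20), replace=False)
    X[:, signal_cols] += 0.8 * y[:, None]
    X = np.maximum(X + 1.0, 0.0)   # shift then rectify: non-negative activations

    train, val, test = stratified_split(y, seed=rng)
    return FeatureDataset(
        X=X,
        y=y,
        feature_names=[f"act{j}" for j in range(D)],
        train_idx=train,
        val_idx=val,
        test_idx=test,
        meta={"signal_idx": np.sort(signal_cols), "block_size": block_size},
    )
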