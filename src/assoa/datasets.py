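"""Labeled feature tables with stratified train/validation/test splits.

The canonical 60/20/20 split mirrors the usual image-classification protocol:
train to fit, validation to steer the optimizer, test touched once at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .space import as_rng

DEFAULT_FRACTIONS = (0.6, 0.2, 0.2)


def stratified_split(
    y: np.ndarray,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed=0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic per-class shuffle-and-slice split.

    Rounding goes train-first within each class, so every class contributes at
    least one training sample whenever it has any.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("split fractions must sum to 1")
    rng = as_rng(seed)
    y = np.asarray(y)
    train, val, test = [], [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        n_train = int(round(fractions[0] * idx.size))
        n_val = int(round(fractions[1] * idx.size))
        n_train = max(1, min(n_train, idx.size))
        train.append(idx[:n_train])
        val.append(idx[n_train : n_train + n_val])
        test.append(idx[n_train + n_val :])
    return (
        np.sort(np.concatenate(train)),
        np.sort(np.concatenate(val)),
        np.sort(np.concatenate(test)),
    )


@dataclass
class FeatureDataset:
    """Samples x features matrix with integer class labels and a fixed split."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ConfigurationError("X must be 2-dimensional (samples x features)")
        if self.y.shape[0] != self.X.shape[0]:
            raise ConfigurationError("label vector length must match the number of rows")
        if np.isnan(self.X).any():
            raise ConfigurationError("feature table contains missing values")
        if np.unique(self.y).size < 2:
            raise ConfigurationError("need at least 2 classes")
        for name, idx in (("train", self.train_idx), ("validation", self.val_idx), ("test", self.test_idx)):
            if len(idx) == 0:
                raise ConfigurationError(f"{name} split is empty")
        all_idx = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if np.unique(all_idx).size != all_idx.size:
            raise ConfigurationError("split index sets overlap")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    @classmethod
    def from_arrays(cls, X, y, feature_names=None, seed=0, fractions=DEFAULT_FRACTIONS, meta=None):
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(X.shape[1])]
        train, val, test = stratified_split(np.asarray(y), fractions, seed)
        return cls(X, np.asarray(y), list(feature_names), train, val, test, meta or {})

    def subset_features(self, mask: np.ndarray) -> "FeatureDataset":
        """Restrict to the selected feature columns, keeping splits."""
        mask = np.asarray(mask, dtype=bool)
        names = [n for n, keep in zip(self.feature_names, mask) if keep]
        return FeatureDataset(
            self.X[:, mask], self.y, names, self.train_idx, self.val_idx, self.test_idx, dict(self.meta)
        )

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.feature_names)
        frame[label_column] = self.y
        return frame
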