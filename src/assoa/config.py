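"""Run configuration schema and feature-table file I/O.

Configs are flat YAML/JSON mappings validated strictly: unknown keys are
rejected with a nearest-match suggestion so typos never silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import FeatureDataset, stratified_split
from .errors import ConfigurationError

TASKS = ("optimize", "select-features", "train-classifier", "compare", "simulate-data")


@dataclass
class RunConfig:
    task: str
    algorithm: str = "assoa"
    agents: int = 20
    iterations: int = 100
    seed: int = 0
    h1: float = 0.99
    G_c: float = 1.9
    P_dp: float = 0.1
    beta: float = 1.5
    dg_low: float = 0.5
    dg_high: float = 1.11
    objective: str = "sphere"
    dims: int = 10
    data: str | None = None
    label_column: str = "label"
    output_dir: str = "runs"
    hidden: int | None = None
    knn_k: int = 5
    runs: int = 30
    algorithms: list = field(default_factory=lambda: ["assoa", "ss", "gwo", "ga"])
    compare_task: str = "fs"
    kind: str = "planted"
    split_fractions: list = field(default_factory=lambda: [0.6, 0.2, 0.2])

    def __post_init__(self):
        if self.task not in TASKS:
            raise ConfigurationError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if not 0.0 <= self.h1 <= 1.0:
            raise ConfigurationError("h1 must lie in [0, 1]")
        if self.agents < 1 or self.iterations < 1:
            raise ConfigurationError("agents and iterations must be positive")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigurationError("split_fractions must sum to 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def config_from_mapping(mapping: dict) -> RunConfig:
    if not isinstance(mapping, dict):
        raise ConfigurationError("config must be a mapping")
    unknown = set(mapping) - _FIELDS
    if unknown:
        key = sorted(unknown)[0]
        hint = difflib.get_close_matches(key, _FIELDS, n=1)
        suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
        raise ConfigurationError(f"unknown config key {key!r}{suggestion}")
    if "task" not in mapping:
        raise ConfigurationError("config must set 'task'")
    return RunConfig(**mapping)


def load_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        mapping = json.loads(text)
    else:
        mapping = yaml.safe_load(text)
    return config_from_mapping(mapping)


def write_config_echo(cfg: RunConfig, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    echo = out_dir / "config_echo.yaml"
    echo.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    return echo


def read_feature_csv(path, label_column: str = "label", seed: int = 0,
                     fractions=(0.6, 0.2, 0.2)) -> FeatureDataset:
    """Load a header-ed CSV into a FeatureDataset with a stratified split."""
    frame = pd.read_csv(path)
    if label_column not in frame.columns:
        raise ConfigurationError(
            f"label column {label_column!r} not found; columns: {list(frame.columns)}"
        )
    y = frame[label_column].to_numpy()
    features = frame.drop(columns=[label_column])
    for col in features.columns:
        coerced = pd.to_numeric(features[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise ConfigurationError(
                f"non-numeric value in column {col!r} at row {row}"
            )
        features[col] = coerced
    X = features.to_numpy(dtype=float)
    train, val, test = stratified_split(y, tuple(fractions), seed)
    return FeatureDataset(
        X=X,
        y=y,
        feature_names=list(features.columns),
        train_idx=train,
        val_idx=val,
        test_idx=test,
    )


def write_feature_csv(data: FeatureDataset, path, label_column: str = "label") -> None:
    data.to_frame(label_column).to_csv(path, index=False)


def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value


def write_json(blob: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(blob, sort_keys=True, indent=2, default=_jsonable) + "\n")
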