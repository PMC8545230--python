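"""Classification metrics, feature-selection run statistics, nonparametric
tests, and the multi-run comparison harness.

The Wilcoxon rank-sum test uses midranks for ties, the exact permutation null
for small pooled samples (m + n <= 20), and the tie-corrected normal
approximation with continuity correction otherwise.  One-way ANOVA is the
classical between/within sum-of-squares decomposition.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import rankdata

from .errors import ConfigurationError
from .feature_selection import FSConfig, select_features
from .mlp import train_mlp_with_optimizer
from .space import ASSOAParams, SSParams
from .baselines import GAParams, GWOParams
from .synthetic import PlantedSpec, generate_planted

EXACT_LIMIT = 20   # pooled-sample size at or below which the exact null is used


# ---------------------------------------------------------------------------
# classification metrics

@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ConfigurationError("confusion counts must be non-negative")
        if self.total == 0:
            raise ConfigurationError("confusion counts must sum to a positive total")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class ClassificationMetrics:
    """Standard binary metrics; ratios with zero denominators are None."""

    accuracy: float
    precision: float | None
    recall: float | None
    specificity: float | None
    f_score: float | None


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def classification_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    accuracy = (c.TP + c.TN) / c.total
    precision = _ratio(c.TP, c.TP + c.FP)
    recall = _ratio(c.TP, c.TP + c.FN)
    specificity = _ratio(c.TN, c.TN + c.FP)
    if precision is None or recall is None or precision + recall == 0:
        f_score = None
    else:
        f_score = 2.0 * precision * recall / (precision + recall)
    return ClassificationMetrics(accuracy, precision, recall, specificity, f_score)


def confusion_from_labels(y_true, y_pred, positive) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
    )


def roc_auc(y_true, scores, positive) -> float:
    """Rank-based AUC (equals the Mann-Whitney U statistic normalized)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == positive]
    neg = scores[y_true != positive]
    if pos.size == 0 or neg.size == 0:
        raise ConfigurationError("AUC needs both positive and negative samples")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# run-set statistics

@dataclass
class RunRecord:
    """One optimizer run: best mask (FS) or model accuracy (MLP), fitness,
    error, convergence curve, seed."""

    fitness: float
    error: float
    curve: np.ndarray
    seed: int
    mask: np.ndarray | None = None


@dataclass
class RunSet:
    algorithm: str
    runs: list[RunRecord] = field(default_factory=list)

    @property
    def fitnesses(self) -> np.ndarray:
        return np.array([r.fitness for r in self.runs])

    @property
    def errors(self) -> np.ndarray:
        return np.array([r.error for r in self.runs])


def fs_run_statistics(rs: RunSet, D: int) -> dict:
    """Mean error, mean select size (fraction of D), and mean / best / worst /
    sd of fitness over the runs (sd with the M-1 denominator)."""
    if not rs.runs:
        raise ConfigurationError("run set is empty")
    fitness = rs.fitnesses
    sizes = np.array(
        [np.count_nonzero(r.mask) / D for r in rs.runs if r.mask is not None], dtype=float
    )
    return {
        "algorithm": rs.algorithm,
        "mean_error": float(rs.errors.mean()),
        "mean_select_size": float(sizes.mean()) if sizes.size else float("nan"),
        "mean_fitness": float(fitness.mean()),
        "best_fitness": float(fitness.min()),
        "worst_fitness": float(fitness.max()),
        "sd_fitness": float(fitness.std(ddof=1)) if fitness.size > 1 else 0.0,
    }


# ---------------------------------------------------------------------------
# hypothesis tests

@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str


def _exact_rank_sum_p(ranks: np.ndarray, m: int, u_obs: float) -> float:
    """Two-sided exact p over all C(m+n, m) group assignments of the midranks.

    The null distribution of U is symmetric about mn/2 (reversing the rank
    order maps assignments bijectively), so the two-sided p-value is the
    probability of a deviation from mn/2 at least as large as observed.
    """
    n_total = ranks.size
    mn_half = m * (n_total - m) / 2.0
    offset = m * (m + 1) / 2.0
    dev_obs = abs(u_obs - mn_half)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n_total), m):
        u = ranks[list(combo)].sum() - offset
        if abs(u - mn_half) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each sample needs at least 2 values")
    m, n = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)          # midranks for ties
    u = ranks[:m].sum() - m * (m + 1) / 2.0

    if m + n <= EXACT_LIMIT:
        p = _exact_rank_sum_p(ranks, m, u)
        return TestResult(statistic=float(u), p_value=float(p), method="exact")

    # tie-corrected normal approximation with continuity correction
    N = m + n
    mu = m * n / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (N * (N - 1))
    var = m * n / 12.0 * ((N + 1) - tie_term)
    if var == 0:
        return TestResult(statistic=float(u), p_value=1.0, method="asymptotic")
    z = (u - mu - math.copysign(0.5, u - mu)) / math.sqrt(var) if u != mu else 0.0
    from scipy.stats import norm

    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return TestResult(statistic=float(u), p_value=float(p), method="asymptotic")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p_value: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ss_total: float


def anova_one_way(groups) -> AnovaResult:
    """Classical one-way ANOVA between/within decomposition."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ConfigurationError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ConfigurationError("each group needs at least 2 values")
    all_values = np.concatenate(groups)
    grand_mean = all_values.mean()
    ss_total = float(np.sum((all_values - grand_mean) ** 2))
    ss_between = float(sum(g.size * (g.mean() - grand_mean) ** 2 for g in groups))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    if ss_total == 0.0:
        raise ConfigurationError("degenerate input: zero total variance")
    k = len(groups)
    N = all_values.size
    df_b, df_w = k - 1, N - k
    if ss_within == 0.0:
        return AnovaResult(float("inf"), 0.0, df_b, df_w, ss_between, ss_within, ss_total)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(f_dist.sf(F, df_b, df_w))
    return AnovaResult(float(F), p, df_b, df_w, ss_between, ss_within, ss_total)


# ---------------------------------------------------------------------------
# comparison harness

DEFAULT_PARAMS = {
    "assoa": lambda n, t_m: ASSOAParams(n=n, t_m=t_m),
    "ss": lambda n, t_m: SSParams(n=n, t_m=t_m),
    "gwo": lambda n, t_m: GWOParams(n=n, t_m=t_m),
    "ga": lambda n, t_m: GAParams(n=n, t_m=t_m),
}


def make_params(algorithm: str, n: int, t_m: int):
    try:
        return DEFAULT_PARAMS[algorithm](n, t_m)
    except KeyError:
        raise ConfigurationError(
            f"no default parameters for algorithm {algorithm!r}; known: {sorted(DEFAULT_PARAMS)}"
        ) from None


@dataclass
class CompareConfig:
    """Scenario configuration for the multi-run comparison.

    Run j of *every* algorithm sees the same dataset realization (paired
    seeds); the first algorithm in the list is the reference for the pairwise
    Wilcoxon tests.
    """

    task: str = "fs"                      # "fs" (wrapper selection) or "mlp" (classifier)
    algorithms: tuple = ("assoa", "ss", "gwo", "ga")
    runs: int = 30
    seed: int = 0
    agents: int = 20
    iterations: int = 50
    spec: PlantedSpec = field(default_factory=PlantedSpec)
    fs_config: FSConfig = field(default_factory=FSConfig)
    hidden: int | None = None

    def __post_init__(self):
        if self.task not in ("fs", "mlp"):
            raise ConfigurationError(f"unknown comparison task {self.task!r}")
        if len(self.algorithms) < 2:
            raise ConfigurationError("need at least 2 algorithms to compare")
        if self.runs < 2:
            raise ConfigurationError("need at least 2 runs for any statistical test")


@dataclass
class ComparisonReport:
    config: CompareConfig
    run_sets: dict
    summary: pd.DataFrame
    wilcoxon: pd.DataFrame
    anova: AnovaResult
    curves: pd.DataFrame

    def to_markdown(self) -> str:
        lines = [
            f"# Algorithm comparison — task: {self.config.task}",
            "",
            f"{self.config.runs} paired runs per algorithm; reference: "
            f"{self.config.algorithms[0]}.",
            "",
            "## Per-algorithm statistics",
            _frame_markdown(self.summary),
            "",
            "## Pairwise Wilcoxon rank-sum (two-sided) vs reference",
            _frame_markdown(self.wilcoxon),
            "",
            "## One-way ANOVA across algorithms",
            f"F({self.anova.df_between}, {self.anova.df_within}) = {self.anova.F:.4f}, "
            f"p = {self.anova.p_value:.4g}",
        ]
        return "\n".join(lines)


def _frame_markdown(frame: pd.DataFrame) -> str:
    def fmt(v):
        return f"{v:.6g}" if isinstance(v, float) else str(v)

    header = "| " + " | ".join(frame.columns) + " |"
    rule = "|" + "|".join("---" for _ in frame.columns) + "|"
    rows = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in frame.itertuples(index=False)]
    return "\n".join([header, rule, *rows])


def _run_seed(base: int, j: int) -> int:
    return (base + 7919 * (j + 1)) % (2**31)


def compare_algorithms(cfg: CompareConfig) -> ComparisonReport:
    """Run each algorithm M times on paired synthetic datasets and emit the
    comparison tables (per-algorithm statistics, pairwise Wilcoxon p-values
    against the reference, one-way ANOVA, and convergence curves)."""
    run_sets = {name: RunSet(algorithm=name) for name in cfg.algorithms}
    curve_rows = []
    for j in range(cfg.runs):
        data = generate_planted(replace(cfg.spec, seed=_run_seed(cfg.seed, j)))
        seed_j = _run_seed(cfg.seed + 104729, j)
        for name in cfg.algorithms:
            params = make_params(name, cfg.agents, cfg.iterations)
            if cfg.task == "fs":
                sel = select_features(data, algorithm=name, params=params, cfg=cfg.fs_config, seed=seed_j)
                record = RunRecord(
                    fitness=sel.best.fitness,
                    error=sel.best.err,
                    curve=sel.optimizer.curve,
                    seed=seed_j,
                    mask=sel.best.mask,
                )
            else:
                res = train_mlp_with_optimizer(
                    data, algorithm=name, params=params, seed=seed_j, hidden=cfg.hidden
                )
                record = RunRecord(
                    fitness=res.optimizer.best_fitness,
                    error=1.0 - res.test_accuracy,
                    curve=res.optimizer.curve,
                    seed=seed_j,
                )
            run_sets[name].runs.append(record)
            for it, value in enumerate(record.curve, start=1):
                curve_rows.append(
                    {"algorithm": name, "run": j, "iteration": it, "best_fitness": value}
                )

    D = cfg.spec.n_features
    summary = pd.DataFrame([fs_run_statistics(run_sets[name], D) for name in cfg.algorithms])
    if cfg.task == "mlp":
        summary["mean_accuracy"] = [1.0 - run_sets[name].errors.mean() for name in cfg.algorithms]

    reference = cfg.algorithms[0]
    ref_errors = run_sets[reference].errors
    wilcoxon_rows = []
    for name in cfg.algorithms[1:]:
        res = wilcoxon_rank_sum(ref_errors, run_sets[name].errors)
        wilcoxon_rows.append(
            {
                "reference": reference,
                "algorithm": name,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    wilcoxon = pd.DataFrame(wilcoxon_rows)
    error_groups = [run_sets[name].errors for name in cfg.algorithms]
    try:
        anova = anova_one_way(error_groups)
    except ConfigurationError:
        # all runs identical across every algorithm: no variance to partition
        N = sum(g.size for g in error_groups)
        anova = AnovaResult(0.0, 1.0, len(error_groups) - 1, N - len(error_groups), 0.0, 0.0, 0.0)
    curves = pd.DataFrame(curve_rows)
    return ComparisonReport(
        config=cfg, run_sets=run_sets, summary=summary, wilcoxon=wilcoxon, anova=anova, curves=curves
    )
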