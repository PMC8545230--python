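"""Statistical comparison of four optimizers on paired feature-selection runs.

Each algorithm solves the same 10 planted datasets with the same seeds; the
report gives per-algorithm fitness statistics, pairwise Wilcoxon rank-sum
p-values against the first (reference) algorithm, and a one-way ANOVA over the
error rates.  p < 0.05 would indicate a significant difference from the
reference.
"""

from assoa import CompareConfig, PlantedSpec, compare_algorithms

cfg = CompareConfig(
    task="fs",
    algorithms=("assoa", "ss", "gwo", "ga"),
    runs=10,
    seed=0,
    agents=20,
    iterations=50,
    spec=PlantedSpec(n_samples=120, n_features=10, k_informative=2, delta=3.0),
)
report = compare_algorithms(cfg)
print(report.to_markdown())
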