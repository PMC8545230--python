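"""The two hypothesis tests used by the comparison harness, stand-alone.

The exact rank-sum p-value for two tiny samples is a closed combinatorial
quantity (here 1/3: of the 6 equally likely rank assignments, 2 are as
extreme as observed); the two-group ANOVA F equals the squared pooled
two-sample t statistic.
"""

import numpy as np

from assoa import anova_one_way, wilcoxon_rank_sum

res = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
print(f"rank-sum U={res.statistic}, exact two-sided p={res.p_value:.4f} (expected 1/3)")

rng = np.random.default_rng(0)
a = rng.normal(size=12)
b = rng.normal(size=12) + 0.8
an = anova_one_way([a, b])
print(f"ANOVA F({an.df_between},{an.df_within}) = {an.F:.4f}, p = {an.p_value:.4g}")
print(f"sum-of-squares check: {an.ss_between:.4f} + {an.ss_within:.4f} = {an.ss_total:.4f}")
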