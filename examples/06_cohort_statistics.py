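"""Recompute cohort lung-function comparisons from printed summaries.

Two-group rows reported as mean +- SD are re-tested with the pooled
two-sided t-test straight from (mean, SD, n); the qualitative sex split is
tested with the Yates-corrected chi-square. A decision-tree helper routes
raw samples to t / Welch / Mann-Whitney based on Shapiro-Wilk and the
variance-ratio F test.
"""

import numpy as np

import lungspan as ls
from lungspan.groupstats import ContingencyTable2x2, SummaryStats

rows = {
    "FVC (L)":      ((3.17, 0.58, 18), (2.50, 0.64, 16)),
    "VC (L)":       ((3.07, 0.56, 18), (2.47, 0.64, 16)),
    "FEV1/FVC (%)": ((81.72, 5.43, 18), (77.50, 6.37, 16)),
    "PEF (L/s)":    ((5.99, 1.57, 18), (4.69, 1.51, 16)),
    "ERV (L)":      ((0.87, 0.31, 18), (0.63, 0.38, 16)),
    "MVV (L/min)":  ((108.30, 22.58, 18), (68.57, 20.64, 16)),
}
print("non-aging vs aging adults, pooled two-sided t from summaries:")
for name, (a, b) in rows.items():
    res = ls.two_sample_t_from_summary(SummaryStats(*a), SummaryStats(*b))
    print(f"  {name:14s} t={res.statistic:6.3f} df={res.df:.0f} p={res.p:.4f}")

sex = ls.yates_chi_square(ContingencyTable2x2(3, 15, 8, 8))
print(f"sex split (3/15 vs 8/8): chi2={sex.statistic:.3f} p={sex.p:.3f} "
      "(Yates continuity correction)")

rng = np.random.default_rng(6)
x, y = rng.normal(0, 1, 40), rng.exponential(1, 40)
rep = ls.check_assumptions(x, y)
print(f"decision tree on raw samples -> {rep.recommendation} "
      "(Shapiro-Wilk flags the exponential sample)")

groups = [rng.normal(m, 1, 12) for m in (0, 0, 0.5, 1.2)]
anova, comps = ls.anova_dunnett(groups, control_index=0, seed=6)
print(f"ANOVA F={anova.statistic:.2f} p={anova.p:.4f}; Dunnett vs control:")
for c in comps:
    print(f"  group {c.extra['comparison']}: t={c.statistic:5.2f} "
          f"adjusted p={c.p:.4f} (MC se {c.extra['mc_se']:.4f})")
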