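"""Group-comparison statistics for the non-single-cell measurements.

Implements the decision tree used for cohort variables such as lung
function: Shapiro-Wilk normality per sample and a variance-ratio F test
route a two-group comparison to a pooled t, Welch t, or Mann-Whitney test;
multi-group comparisons use one-way ANOVA with Dunnett many-to-one
follow-up; 2x2 qualitative tables use the chi-square with Yates continuity
correction. Two-group t-tests can be computed directly from printed
summaries (mean, SD, n), which is how the cohort table is recomputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

log = logging.getLogger("lungspan")

__all__ = [
    "SummaryStats",
    "ContingencyTable2x2",
    "TestResult",
    "check_assumptions",
    "two_sample_t_from_summary",
    "mann_whitney_test",
    "yates_chi_square",
    "anova_dunnett",
    "dunnett_max_t_null",
]


@dataclass(frozen=True)
class SummaryStats:
    """One group's printed summary: mean, SD, n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    method: str
    extra: dict = field(default_factory=dict)


@dataclass
class AssumptionReport:
    shapiro: list[TestResult]
    variance_ratio: TestResult | None
    recommendation: str  # "t-test" | "welch-t" | "mann-whitney"


def check_assumptions(x, y, alpha: float = 0.05) -> AssumptionReport:
    """Shapiro-Wilk per sample + variance-ratio F -> recommended test.

    Both samples normal and variances homogeneous -> pooled t; normal but
    heterogeneous -> Welch t; any non-normal (or constant) sample ->
    Mann-Whitney.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 3:
        raise ValueError("need >= 3 observations per sample")
    shapiro: list[TestResult] = []
    normal = True
    for s in (x, y):
        if np.ptp(s) == 0:
            log.warning("constant sample: Shapiro W undefined; "
                        "falling back to Mann-Whitney")
            shapiro.append(TestResult(np.nan, s.size, np.nan, "shapiro-wilk"))
            normal = False
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w, p = scipy.stats.shapiro(s)
        shapiro.append(TestResult(float(w), s.size, float(p), "shapiro-wilk"))
        normal &= p > alpha

    vr = None
    if normal:
        v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
        if v1 >= v2:
            f, dfn, dfd = v1 / v2, x.size - 1, y.size - 1
        else:
            f, dfn, dfd = v2 / v1, y.size - 1, x.size - 1
        p_f = min(1.0, 2.0 * scipy.stats.f.sf(f, dfn, dfd))
        vr = TestResult(float(f), dfn, float(p_f), "variance-ratio",
                        {"df_den": dfd})
        rec = "t-test" if p_f > alpha else "welch-t"
    else:
        rec = "mann-whitney"
    return AssumptionReport(shapiro, vr, rec)


def two_sample_t_from_summary(
    a: SummaryStats, b: SummaryStats, pooled: bool = True
) -> TestResult:
    """Two-sided two-sample t-test from printed mean/SD/n summaries.

    Pooled: sp^2 = ((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2), df = n1+n2-2.
    Welch: Satterthwaite df. Identical to the raw-data test computed on
    samples with those summaries.
    """
    res = scipy.stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=pooled)
    if pooled:
        df = a.n + b.n - 2
        method = "t-test (pooled)"
    else:
        v1, v2 = a.sd ** 2 / a.n, b.sd ** 2 / b.n
        df = (v1 + v2) ** 2 / (v1 ** 2 / (a.n - 1) + v2 ** 2 / (b.n - 1))
        method = "t-test (welch)"
    return TestResult(float(res.statistic), float(df), float(res.pvalue), method)


def mann_whitney_test(x, y) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact enumeration for small samples without ties (both n <= 20);
    normal approximation with tie correction (and continuity correction)
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 20 and not ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), np.nan, float(min(1.0, res.pvalue)),
                      f"mann-whitney ({method})")


def yates_chi_square(t: ContingencyTable2x2) -> TestResult:
    """Chi-square with Yates continuity correction on a 2x2 table.

    chi2 = n * (max(0, |ad - bc| - n/2))^2 / ((a+b)(c+d)(a+c)(b+d)), df=1.
    Any zero marginal gives p = 1 with a warning.
    """
    a, b, c, d, n = t.a, t.b, t.c, t.d, t.n
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        log.warning("zero marginal in 2x2 table; chi-square undefined, p = 1")
        return TestResult(0.0, 1, 1.0, "chi-square (yates)")
    num = n * max(0.0, abs(a * d - b * c) - n / 2.0) ** 2
    chi2 = num / float(np.prod(margins, dtype=float))
    p = float(scipy.stats.chi2.sf(chi2, 1))
    return TestResult(float(chi2), 1, p, "chi-square (yates)")


def dunnett_max_t_null(
    group_sizes: list[int],
    control_index: int,
    n_draws: int = 100_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Monte Carlo sample of the null max |t| over many-to-one comparisons.

    Group means are N(0, 1/n_i), the common variance estimate is
    chi2_df/df with df = N - k; the draws share one variance per replicate,
    reproducing the correlation between the comparisons.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    sizes = np.asarray(group_sizes, dtype=float)
    k = sizes.size
    df = int(sizes.sum()) - k
    means = rng.standard_normal((n_draws, k)) / np.sqrt(sizes)
    s2 = rng.chisquare(df, size=n_draws) / df
    others = [i for i in range(k) if i != control_index]
    se = np.sqrt(1.0 / sizes[others] + 1.0 / sizes[control_index])
    t = (means[:, others] - means[:, [control_index]]) / (
        np.sqrt(s2)[:, None] * se[None, :])
    return np.abs(t).max(axis=1)


def anova_dunnett(
    groups: list[np.ndarray],
    control_index: int = 0,
    n_draws: int = 100_000,
    seed: int = 0,
    null_max_t: np.ndarray | None = None,
) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA plus Dunnett many-to-one adjusted comparisons.

    The Dunnett adjusted p for comparison i is P(max_j |T_j| >= |t_i|)
    under the joint null of the correlated t statistics, estimated by
    seeded Monte Carlo (``n_draws`` replicates; the Monte Carlo standard
    error is reported in ``extra``). The adjusted p is floored at the
    unadjusted two-sided p, which it cannot undercut analytically.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if not 0 <= control_index < len(groups):
        raise ValueError("control index out of range")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    sizes = [g.size for g in groups]
    df = sum(sizes) - len(groups)
    grand = np.concatenate(groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within == 0:
        anova = TestResult(0.0, len(groups) - 1, 1.0, "anova",
                           {"df_within": df})
        f_res_p = 1.0
    else:
        f_stat, f_res_p = scipy.stats.f_oneway(*groups)
        anova = TestResult(float(f_stat), len(groups) - 1, float(f_res_p),
                           "anova", {"df_within": df})
    s2 = ss_within / df if df > 0 else 0.0
    if null_max_t is None:
        rng = np.random.default_rng(seed)
        null_max_t = dunnett_max_t_null(sizes, control_index, n_draws, rng)
    control = groups[control_index]
    comparisons: list[TestResult] = []
    for i, g in enumerate(groups):
        if i == control_index:
            continue
        if s2 == 0:
            comparisons.append(TestResult(
                0.0, df, 1.0, "dunnett", {"mc_se": 0.0, "comparison": i}))
            continue
        se = np.sqrt(s2 * (1.0 / g.size + 1.0 / control.size))
        t = (g.mean() - control.mean()) / se
        p_adj = float((null_max_t >= abs(t)).mean())
        mc_se = float(np.sqrt(p_adj * (1 - p_adj) / null_max_t.size))
        p_raw = float(2 * scipy.stats.t.sf(abs(t), df))
        comparisons.append(TestResult(
            float(t), df, max(p_adj, p_raw), "dunnett",
            {"mc_se": mc_se, "p_unadjusted": p_raw, "comparison": i}))
    return anova, comparisons
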