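"""Statistical toolkit: dispersion summaries, one-way ANOVA with two-sided
Tukey HSD, and OLS regression with a two-tailed slope t-test and R².

These are the exact procedures used throughout the congression analyses:
group scatter is summarized as mean ± SD with 95% confidence intervals for
both; multi-group comparisons use one-way ANOVA followed by pairwise
two-sided Tukey HSD at the 5% level (Tukey–Kramer for unbalanced groups,
which the cell-biology cohorts always are); trend analyses use ordinary
least squares with the slope tested by a two-tailed t-test.

The ANOVA sum-of-squares decomposition and the Tukey q statistic are
computed here explicitly (they are reported, not just the p-values);
distribution functions come from scipy (``t``, ``chi2``, ``f``,
``studentized_range``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "TukeyResult",
    "OlsResult",
    "significance_stars",
    "summarize_group",
    "one_way_anova",
    "tukey_hsd",
    "ols_slope_test",
    "comparisons_table",
]


@dataclass(frozen=True)
class GroupSummary:
    """n, mean, sample SD and 95% CIs of mean (t) and SD (chi-square)."""

    n: int
    mean: float
    sd: float
    ci95_mean: tuple[float, float]
    ci95_sd: tuple[float, float]


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float
    ms_within: float


@dataclass(frozen=True)
class TukeyResult:
    """One pairwise comparison of a Tukey HSD family."""

    group_a: str
    group_b: str
    mean_difference: float  # mean_a - mean_b
    q_statistic: float
    p_adjusted: float
    stars: str


@dataclass(frozen=True)
class OlsResult:
    slope: float
    intercept: float
    p_two_tailed: float
    r_squared: float
    stderr_slope: float
    n: int
    exact_fit: bool


def significance_stars(p: float) -> str:
    """Figure-legend star convention: * <0.05, ** <0.01, *** <0.001,
    **** <0.0001; 'n.s.' otherwise."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def summarize_group(values: Sequence[float], confidence: float = 0.95) -> GroupSummary:
    """Mean, sample SD, and CIs for both (t for the mean, chi² for the SD)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("summarize_group requires at least 2 values")
    n = x.size
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    alpha = 1.0 - confidence
    tcrit = sps.t.ppf(1 - alpha / 2, df=n - 1)
    half = tcrit * sd / np.sqrt(n)
    chi_lo = sps.chi2.ppf(1 - alpha / 2, df=n - 1)
    chi_hi = sps.chi2.ppf(alpha / 2, df=n - 1)
    sd_ci = (
        float(np.sqrt((n - 1) * sd**2 / chi_lo)),
        float(np.sqrt((n - 1) * sd**2 / chi_hi)) if chi_hi > 0 else float("inf"),
    )
    return GroupSummary(
        n=n, mean=mean, sd=sd,
        ci95_mean=(mean - float(half), mean + float(half)),
        ci95_sd=sd_ci,
    )


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("at least 2 groups required")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise ValueError(f"group {i} has n < 2")
    return arrs


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA (fixed effects, between/within decomposition)."""
    arrs = _check_groups(groups)
    n_total = sum(g.size for g in arrs)
    grand = sum(g.sum() for g in arrs) / n_total
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in arrs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    dfb = len(arrs) - 1
    dfw = n_total - len(arrs)
    if ssw <= 0:
        raise ValueError("zero within-group variance: ANOVA is degenerate")
    f = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(f, dfb, dfw))
    return AnovaResult(
        f_statistic=float(f), df_between=dfb, df_within=dfw, p_value=p,
        ss_between=float(ssb), ss_within=float(ssw), ms_within=float(ssw / dfw),
    )


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> list[TukeyResult]:
    """Pairwise two-sided Tukey HSD with Tukey–Kramer unequal-n correction.

    The studentized-range statistic for groups i, j is

        q = |mean_i - mean_j| / sqrt(MSW * (1/n_i + 1/n_j) / 2)

    with MSW the ANOVA within-group mean square; the adjusted p-value is
    the survival function of the studentized-range distribution with k
    groups and the within df.
    """
    arrs = _check_groups(groups)
    if labels is None:
        labels = [f"group_{i}" for i in range(len(arrs))]
    if len(labels) != len(arrs):
        raise ValueError("labels must match the number of groups")
    anova = one_way_anova(arrs)
    k = len(arrs)
    out: list[TukeyResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(arrs[i].mean() - arrs[j].mean())
            se = np.sqrt(anova.ms_within * (1 / arrs[i].size + 1 / arrs[j].size) / 2)
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, anova.df_within))
            p = min(max(p, 0.0), 1.0)
            out.append(TukeyResult(
                group_a=str(labels[i]), group_b=str(labels[j]),
                mean_difference=diff, q_statistic=float(q),
                p_adjusted=p, stars=significance_stars(p),
            ))
    return out


def comparisons_table(results: Sequence[TukeyResult]) -> pd.DataFrame:
    """Tidy comparisons table (group_a, group_b, diff, q, p_adj, stars)."""
    return pd.DataFrame([
        {"group_a": r.group_a, "group_b": r.group_b,
         "diff": r.mean_difference, "q": r.q_statistic,
         "p_adj": r.p_adjusted, "stars": r.stars}
        for r in results
    ])


def ols_slope_test(x: Sequence[float], y: Sequence[float]) -> OlsResult:
    """Ordinary least squares of y on x with a two-tailed slope t-test.

    A numerically exact fit (zero residual variance) is reported with
    p = 0 and the ``exact_fit`` flag set; x without variance is an error.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have the same length")
    if xa.size < 3:
        raise ValueError("OLS slope test requires n >= 3")
    if np.var(xa) == 0:
        raise ValueError("x has zero variance: slope undefined")

    res = sps.linregress(xa, ya)
    slope, intercept = float(res.slope), float(res.intercept)
    resid = ya - (slope * xa + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((ya - ya.mean()) ** 2).sum())
    if ss_tot == 0:
        # constant y: slope 0 carries no information
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    exact = ss_res <= 1e-12 * max(ss_tot, 1.0)
    if exact:
        p = 0.0 if ss_tot > 0 else 1.0
    else:
        p = float(res.pvalue)
    return OlsResult(
        slope=slope, intercept=intercept, p_two_tailed=p, r_squared=float(r2),
        stderr_slope=float(res.stderr), n=int(xa.size), exact_fit=bool(exact),
    )
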