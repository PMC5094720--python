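"""Statistics over quantified clusters: time-course trends per element.

For each element and cell compartment the quantified weight fractions at the
stimulation time points (0, 1, 2 h) are summarised and tested:

* group summaries: mean with +/-1 RSD over replicate cells, flagged when the
  RSD band exceeds 25% of the mean;
* ordinary least squares of value on time over individual cluster values
  (not time-point means), giving the slope beta0 in ppb/h, r^2 and a 95%
  t-based confidence interval; slope and CI are suppressed when r^2 < 0.5;
* one-way ANOVA (F, p) across time groups and, for the least-normal rows, a
  tie-corrected Kruskal-Wallis test (chi^2-distributed H, asymptotic p, with
  an exact-permutation option for tiny samples);
* normality grading of the regression standardized residuals from the P-P
  plot correlation (Blom plotting positions by default): +++ / ++ / +.

No multiple-testing correction is applied by default, matching the small
exploratory design; a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TimeCourse",
    "TrendRow",
    "group_summary",
    "time_regression",
    "anova_oneway",
    "kruskal_wallis",
    "normality_grade",
    "build_trend_table",
]

_PPB = 1e-9


@dataclass
class TimeCourse:
    """Weight-fraction observations of one element in one compartment."""

    element: str
    compartment: str
    times_h: np.ndarray
    values: np.ndarray  # weight fractions (dimensionless)
    cell_labels: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_h.shape != self.values.shape:
            raise ValueError("times and values must align")
        if np.any(self.values < 0):
            raise ValueError("weight fractions must be non-negative")

    def groups(self) -> dict[float, np.ndarray]:
        return {t: self.values[self.times_h == t] for t in np.unique(self.times_h)}


@dataclass
class TrendRow:
    element: str
    compartment: str
    normality_grade: str | None
    r2: float
    beta0_ppb_per_h: float | None  # suppressed (None) when r2 < 0.5
    ci95_ppb_per_h: tuple[float, float] | None
    trend: str  # "+", "-", "const."
    anova_f: float
    anova_p: float
    kw_chi2: float | None
    kw_p: float | None
    group_means: dict[float, float] = field(default_factory=dict)
    group_rsd_flags: dict[float, bool] = field(default_factory=dict)
    bold: bool = False  # r2 >= 0.5 (slope reported)
    significant: bool = False  # ANOVA p below threshold


def group_summary(values: Iterable[float]):
    """Mean, sample SD, n and the high-variance flag for one time group.

    The flag is set when the +/-1 RSD band exceeds 25% of the mean (sample
    standard deviation, n-1 denominator; zero for a single observation).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty group")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    flag = bool(sd > 0.25 * abs(mean)) if mean != 0 else bool(sd > 0)
    return mean, sd, int(arr.size), flag


def time_regression(tc: TimeCourse, ci_level: float = 0.95, const_r2: float = 0.05):
    """OLS of weight fraction on time over individual observations.

    Returns ``(beta0_ppb_per_h, r2, (ci_lo, ci_hi), trend)``; the slope and
    CI are in ppb per hour.  The trend is the slope sign, or "const." when
    r^2 < ``const_r2`` and the CI spans zero.
    """
    if tc.values.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(tc.times_h).size < 2:
        raise ValueError("need at least 2 distinct time points")
    x = sm.add_constant(tc.times_h)
    fit = sm.OLS(tc.values, x).fit()
    slope = float(fit.params[1]) / _PPB
    r2 = float(fit.rsquared)
    ci = fit.conf_int(alpha=1.0 - ci_level)
    lo, hi = float(ci[1, 0]) / _PPB, float(ci[1, 1]) / _PPB
    if r2 < const_r2 and lo <= 0.0 <= hi:
        trend = "const."
    else:
        trend = "+" if slope >= 0 else "-"
    return slope, r2, (lo, hi), trend


def regression_residuals(tc: TimeCourse) -> np.ndarray:
    """Standardized OLS residuals of the value-vs-time regression."""
    x = sm.add_constant(tc.times_h)
    fit = sm.OLS(tc.values, x).fit()
    resid = np.asarray(fit.resid)
    sd = resid.std(ddof=1)
    if sd == 0:
        return np.zeros_like(resid)
    return resid / sd


def anova_oneway(groups: Sequence[np.ndarray]):
    """Classical one-way ANOVA F and p across time groups.

    Identical values in every group give (F=0, p=1) rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    f, p = sps.f_oneway(*groups)
    if not np.isfinite(f):  # zero within-group variance, unequal means
        return float("inf"), 0.0
    return float(f), float(p)


def _kw_statistic(groups: Sequence[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H by the rank formula (oracle-friendly)."""
    allv = np.concatenate(groups)
    n = allv.size
    ranks = sps.rankdata(allv)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(allv, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie == 0:
        return 0.0
    return h / tie


def kruskal_wallis(groups: Sequence[np.ndarray], permutation: bool = False):
    """Tie-corrected Kruskal-Wallis H with chi-square asymptotic p.

    ``permutation=True`` replaces the asymptotic p with the exact
    permutation-null probability P(H >= H_obs) over all assignments of the
    pooled values to the group sizes (small N only).  All-identical values
    give (H=0, p=1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    if permutation:
        sizes = [len(g) for g in groups]
        n = allv.size
        if n > 9:
            raise ValueError("exact permutation p only supported for N <= 9")
        count = 0
        total = 0
        h_obs = _kw_statistic(groups)
        for perm in permutations(range(n)):
            vals = allv[list(perm)]
            gs, start = [], 0
            for s in sizes:
                gs.append(vals[start : start + s])
                start += s
            if _kw_statistic(gs) >= h_obs - 1e-12:
                count += 1
            total += 1
        p = count / total
    return float(h), float(p)


def normality_grade(
    residuals: np.ndarray,
    thresholds: tuple[float, float] = (0.99, 0.95),
    plotting_positions: str = "blom",
):
    """Grade normality of standardized residuals from the P-P correlation.

    The grade reflects how well the points of a probability-probability plot
    align with y = x: the correlation between the theoretical normal
    cumulative probabilities of the sorted standardized residuals and their
    empirical plotting positions (Blom ``(i - 3/8)/(n + 1/4)`` by default,
    Hazen ``(i - 1/2)/n`` as an option).  Returns (grade, r_pp) with grade
    "+++" for r >= 0.99, "++" for r >= 0.95, "+" otherwise.
    """
    resid = np.asarray(residuals, dtype=float)
    if resid.size < 3:
        raise ValueError("need at least 3 residuals")
    sd = resid.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance residuals: grade undefined")
    z = np.sort((resid - resid.mean()) / sd)
    n = z.size
    i = np.arange(1, n + 1)
    if plotting_positions == "blom":
        emp = (i - 0.375) / (n + 0.25)
    elif plotting_positions == "hazen":
        emp = (i - 0.5) / n
    else:
        raise ValueError(f"unknown plotting positions {plotting_positions!r}")
    theo = sps.norm.cdf(z)
    r = float(np.corrcoef(theo, emp)[0, 1])
    hi, mid = thresholds
    grade = "+++" if r >= hi else ("++" if r >= mid else "+")
    return grade, r


def build_trend_table(
    timecourses: Iterable[TimeCourse],
    significance: float = 0.05,
    r2_suppress: float = 0.5,
    kw_grades: tuple[str, ...] = ("+",),
    fdr_correct: bool = False,
) -> pd.DataFrame:
    """Per-element, per-compartment trend table.

    Applies the suppression rule (slope and CI omitted when r^2 < 0.5), the
    bold/italic flags (bold when the slope is reported or the test p-value
    is below the significance threshold) and runs Kruskal-Wallis only for
    the rows graded least normal.  Missing or degenerate rows are emitted
    with absent cells rather than dropped.
    """
    rows = []
    for tc in timecourses:
        groups = list(tc.groups().values())
        rec: dict = {"element": tc.element, "compartment": tc.compartment}
        try:
            slope, r2, ci, trend = time_regression(tc)
        except ValueError:
            rec.update(
                r2=np.nan, beta0_ppb_per_h=np.nan, ci95_lo=np.nan, ci95_hi=np.nan,
                trend="", normality_grade="", anova_f=np.nan, anova_p=np.nan,
                kw_chi2=np.nan, kw_p=np.nan, bold=False, significant=False,
                high_variance_any=False,
            )
            rows.append(rec)
            continue
        try:
            grade, _ = normality_grade(regression_residuals(tc))
        except ValueError:
            grade = ""
        f, p = anova_oneway(groups)
        kw_h = kw_p = np.nan
        if grade in kw_grades:
            kw_h, kw_p = kruskal_wallis(groups)
        suppressed = r2 < r2_suppress
        flags = [group_summary(g)[3] for g in groups]
        rec.update(
            r2=r2,
            beta0_ppb_per_h=np.nan if suppressed else slope,
            ci95_lo=np.nan if suppressed else ci[0],
            ci95_hi=np.nan if suppressed else ci[1],
            trend=trend,
            normality_grade=grade,
            anova_f=f,
            anova_p=p,
            kw_chi2=kw_h,
            kw_p=kw_p,
            bold=not suppressed,
            significant=bool(p < significance),
            high_variance_any=bool(any(flags)),
        )
        for t, g in tc.groups().items():
            mean, sd, n, flag = group_summary(g)
            rec[f"mean_{t:g}h"] = mean
            rec[f"rsd_{t:g}h"] = sd
            rec[f"flag_{t:g}h"] = flag
        rows.append(rec)
    table = pd.DataFrame(rows)
    if fdr_correct and len(table) and table["anova_p"].notna().any():
        mask = table["anova_p"].notna()
        adj = multipletests(table.loc[mask, "anova_p"], method="fdr_bh")[1]
        table.loc[mask, "anova_p_fdr"] = adj
        table.loc[mask, "significant"] = adj < significance
    return table
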