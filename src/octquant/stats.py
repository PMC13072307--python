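"""Reliability and group-comparison statistics.

Implements the two-way random-effects absolute-agreement intraclass
correlation (single and average measures, F-based 95% CIs), the
Spearman-Brown aggregation linking them, coefficient of variation, weekly
percentage change, the strict >5% eligibility filter, Kruskal-Wallis with
Dunn's Bonferroni-adjusted post-hoc comparisons, the Mann-Whitney U test
(exact for small samples), and the ``n = 1 + 2C(s/d)^2`` sample-size
formula.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .volio import RatingTable

__all__ = [
    "IccResult",
    "LongitudinalSeries",
    "GroupComparison",
    "icc_two_way_random_absolute",
    "spearman_brown",
    "interpret_icc",
    "coefficient_of_variation",
    "weekly_change",
    "filter_eligible",
    "compare_groups_kw_dunn",
    "mann_whitney",
    "sample_size",
]

EXACT_MWU_MAX_N = 8  # per-group size at or below which the exact null is used


@dataclass
class IccResult:
    icc_single: float
    icc_average: float
    ci95_single: tuple[float, float]
    ci95_average: tuple[float, float]
    f_value: float
    df1: int
    df2: int
    p_value: float
    model_tag: str = "two-way random, absolute agreement"

    def __post_init__(self) -> None:
        for name in ("icc_single", "icc_average"):
            v = getattr(self, name)
            if not -1 < v <= 1 + 1e-12:
                raise ValueError(f"{name}={v} outside (-1, 1]")
        if self.df1 < 1 or self.df2 < 1:
            raise ValueError("degrees of freedom must be >= 1")

    def as_table(self) -> pd.DataFrame:
        """Single/average rows with CI, F and significance."""
        return pd.DataFrame(
            {
                "Intraclass Correlation": [self.icc_single, self.icc_average],
                "CI95 Lower": [self.ci95_single[0], self.ci95_average[0]],
                "CI95 Upper": [self.ci95_single[1], self.ci95_average[1]],
                "F": [self.f_value, self.f_value],
                "df1": [self.df1, self.df1],
                "df2": [self.df2, self.df2],
                "Sig": [self.p_value, self.p_value],
            },
            index=["Single Measures", "Average Measures"],
        )


@dataclass
class LongitudinalSeries:
    """Ordered per-eye (timepoint, % opacity) trajectory."""

    eye_id: str
    timepoints: Sequence[float]
    percents: Sequence[float]
    group: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        p = np.asarray(self.percents, dtype=float)
        if t.size != p.size:
            raise ValueError("timepoints and percents differ in length")
        if t.size and not (np.diff(t) > 0).all():
            raise ValueError("timepoints must be strictly increasing")
        if ((p < 0) | (p > 100)).any():
            raise ValueError("percents must lie in [0, 100]")


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    method: str
    pairwise: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# ICC


def _anova_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((values - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_two_way_random_absolute(table: RatingTable) -> IccResult:
    """ICC(A,1) and ICC(A,k) under the two-way random-effects
    absolute-agreement model, with F-based 95% confidence intervals.

    Raises if both subject and error variance vanish (ICC undefined).
    """
    values = np.asarray(table.values, dtype=float)
    n, k = values.shape
    msr, msc, mse = _anova_mean_squares(values)
    if msr == 0 and mse == 0:
        raise ValueError("zero subject and error variance: ICC undefined")

    denom_single = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc_single = (msr - mse) / denom_single if denom_single != 0 else 1.0
    denom_avg = msr + (msc - mse) / n
    icc_average = (msr - mse) / denom_avg if denom_avg != 0 else 1.0

    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse > 0:
        f_value = msr / mse
        p_value = float(sps.f.sf(f_value, df1, df2))
    else:
        f_value, p_value = math.inf, 0.0

    ci_single = _icc_a1_ci(icc_single, msr, msc, mse, n, k)
    ci_average = (
        spearman_brown(ci_single[0], k),
        spearman_brown(ci_single[1], k),
    )
    return IccResult(
        icc_single=float(icc_single),
        icc_average=float(icc_average),
        ci95_single=ci_single,
        ci95_average=ci_average,
        f_value=float(f_value),
        df1=df1,
        df2=df2,
        p_value=p_value,
    )


def _icc_a1_ci(
    icc: float, msr: float, msc: float, mse: float, n: int, k: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Satterthwaite F-based CI for the single-measures absolute-agreement ICC."""
    if mse == 0 and msc == 0:
        return (icc, icc)  # degenerate: perfect agreement
    one_minus = max(1.0 - icc, 1e-15)
    a = k * icc / (n * one_minus)
    b = 1.0 + k * icc * (n - 1) / (n * one_minus)
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else (n - 1) * (k - 1)
    f_lo = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = sps.f.ppf(1 - alpha / 2, v, n - 1)
    mix = k * msc + (k * n - k - n) * mse
    lower = n * (msr - f_lo * mse) / (f_lo * mix + n * msr)
    upper = n * (f_up * msr - mse) / (mix + n * f_up * msr)
    lower = float(np.clip(lower, -1.0, 1.0))
    upper = float(np.clip(upper, -1.0, 1.0))
    lower = min(lower, icc)
    upper = max(upper, icc)
    return (lower, upper)


def spearman_brown(icc_single: float, k: int | float) -> float:
    """Aggregate a single-measure reliability to the mean of ``k`` measures:
    ``k*r / (1 + (k-1)*r)``."""
    if not -1 < icc_single <= 1:
        raise ValueError(f"icc_single={icc_single} outside (-1, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    return k * icc_single / (1.0 + (k - 1) * icc_single)


def interpret_icc(value: float) -> str:
    """Map an ICC to {poor, fair, good, excellent}; 0.5 and 0.75 belong to
    the upper interval, excellent requires strictly > 0.9."""
    if not -1 <= value <= 1:
        raise ValueError(f"ICC {value} outside [-1, 1]")
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "fair"
    if value <= 0.9:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# longitudinal metrics


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Percent CoV: 100 * sample SD (n-1 denominator) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CoV needs >= 2 values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError(f"CoV undefined for mean <= 0 (mean={mean})")
    return 100.0 * v.std(ddof=1) / mean


def weekly_change(series: LongitudinalSeries) -> list[float]:
    """Percent change between consecutive timepoints; negative = reduction."""
    p = np.asarray(series.percents, dtype=float)
    if p.size < 2:
        raise ValueError("need >= 2 timepoints")
    out = []
    for i in range(p.size - 1):
        if p[i] == 0:
            raise ValueError(
                f"zero baseline at timepoint index {i}: percent change undefined"
            )
        out.append(100.0 * (p[i + 1] - p[i]) / p[i])
    return out


def filter_eligible(
    measurements: pd.DataFrame,
    min_percent: float = 5.0,
    baseline_label: str = "baseline",
    pretreatment_label: str = "pre",
) -> pd.DataFrame:
    """Keep eyes whose opacity increase from pre-injury baseline to the
    pre-treatment timepoint is strictly greater than ``min_percent``.

    Expects columns ``eye_id``, ``timepoint``, ``percent_opacity``.  Eyes
    lacking a baseline (or pre-treatment) row are excluded with a warning.
    Returns the eligible subset of ``measurements`` (all timepoints of the
    eligible eyes).
    """
    required = {"eye_id", "timepoint", "percent_opacity"}
    if not required <= set(measurements.columns):
        raise ValueError(f"measurements need columns {sorted(required)}")
    keep = []
    for eye, grp in measurements.groupby("eye_id", sort=False):
        tp = grp.set_index("timepoint")["percent_opacity"]
        if baseline_label not in tp.index or pretreatment_label not in tp.index:
            warnings.warn(
                f"eye {eye!r} lacks a {baseline_label!r} or "
                f"{pretreatment_label!r} measurement; excluded"
            )
            continue
        delta = float(tp[pretreatment_label]) - float(tp[baseline_label])
        if delta > min_percent:
            keep.append(eye)
    return measurements[measurements["eye_id"].isin(keep)].copy()


# ---------------------------------------------------------------------------
# group comparisons


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact null distribution when both groups have <= 8 observations and no
    ties span the groups; otherwise the tie-corrected normal approximation.
    Returns (U of the first sample, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return float(a.size * b.size / 2.0), 1.0  # all values identical
    method = (
        "exact"
        if (a.size <= EXACT_MWU_MAX_N and b.size <= EXACT_MWU_MAX_N and not has_ties)
        else "asymptotic"
    )
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _dunn_pairwise(groups: Mapping[str, np.ndarray]) -> list[dict]:
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = sps.rankdata(pooled)
    N = pooled.size
    # tie correction term for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (N - 1)))
    base_var = N * (N + 1) / 12.0 - tie_term

    mean_ranks, sizes = {}, {}
    start = 0
    for g in labels:
        ng = groups[g].size
        mean_ranks[g] = float(ranks[start : start + ng].mean())
        sizes[g] = ng
        start += ng

    m = len(labels) * (len(labels) - 1) // 2
    out = []
    for g1, g2 in itertools.combinations(labels, 2):
        se = math.sqrt(base_var * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p_adj = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m)  # Bonferroni
        out.append({"group_a": g1, "group_b": g2, "z": z, "p_adj": p_adj})
    return out


def compare_groups_kw_dunn(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Kruskal-Wallis omnibus (tie-corrected) plus Dunn's z pairwise tests
    with Bonferroni adjustment.  Two groups delegate to Mann-Whitney."""
    clean = {str(g): np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(clean) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in clean.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has n={v.size} < 2")
    if len(clean) == 2:
        (a, b) = clean.values()
        u, p = mann_whitney(a, b)
        return GroupComparison(statistic=u, p_value=p, method="mann-whitney")
    pooled = np.concatenate(list(clean.values()))
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*clean.values())
    return GroupComparison(
        statistic=float(h),
        p_value=float(p),
        method="kruskal-wallis + dunn (bonferroni)",
        pairwise=_dunn_pairwise(clean),
    )


# ---------------------------------------------------------------------------
# sample size


def sample_size(effect_d: float, sd_s: float, C: float = 10.51) -> int:
    """Per-group n from ``n = 1 + 2 C (s/d)^2``, rounded up.

    ``C`` defaults to 10.51 (two-sided alpha 0.05); the continuous output is
    rounded to the next integer since a fractional group size is not usable.
    """
    if effect_d <= 0:
        raise ValueError("effect size d must be > 0")
    if sd_s < 0 or C <= 0:
        raise ValueError("need s >= 0 and C > 0")
    return math.ceil(1.0 + 2.0 * C * (sd_s / effect_d) ** 2)
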