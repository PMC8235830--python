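"""Method-comparison statistics.

Implements the agreement machinery used to contrast estimation methods
across a collection of series: RMSE standardisation of effect
estimates, direction alignment, Bland-Altman mean difference and 95%
limits of agreement (log scale for standard errors, reported as
geometric mean ratios), confidence-interval width comparison on a
common [-0.5, 0.5] scale, p-value categorisation, percent agreement
with unweighted Cohen's kappa, and autocorrelation summaries stratified
by series length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .estimators import FitResult

__all__ = [
    "StandardizedEstimates", "AgreementSummary", "ConcordanceTable",
    "standardize_fit", "align_direction", "bland_altman",
    "ci_width_comparison", "categorize_p", "concordance",
    "autocorrelation_summary", "kappa_adjective",
]


class ComparisonError(ValueError):
    pass


# ---------------------------------------------------------------------------
# standardisation


@dataclass(frozen=True)
class StandardizedEstimates:
    """Per-effect estimates divided by the series' OLS RMSE.

    p-values and degrees of freedom pass through untouched; only the
    scale of estimates, standard errors and CI bounds changes.
    """

    level_change: float
    slope_change: float
    level_se: float
    slope_se: float
    level_ci: Tuple[float, float]
    slope_ci: Tuple[float, float]
    level_p: float
    slope_p: float
    method: str


def standardize_fit(fit: FitResult, ols_rmse: float, design) -> StandardizedEstimates:
    """Divide level/slope estimates, SEs and CI bounds by the OLS RMSE."""
    if not ols_rmse > 0:
        raise ComparisonError("standardisation requires a positive OLS RMSE; "
                              "zero-RMSE series are excluded upstream")
    i = design.roles["level_change"]
    j = design.roles["slope_change"]
    r = ols_rmse
    return StandardizedEstimates(
        level_change=float(fit.beta[i]) / r,
        slope_change=float(fit.beta[j]) / r,
        level_se=float(fit.se[i]) / r,
        slope_se=float(fit.se[j]) / r,
        level_ci=(float(fit.ci[i, 0]) / r, float(fit.ci[i, 1]) / r),
        slope_ci=(float(fit.ci[j, 0]) / r, float(fit.ci[j, 1]) / r),
        level_p=float(fit.p[i]),
        slope_p=float(fit.p[j]),
        method=fit.method,
    )


def align_direction(a: float, b: float,
                    anchor: Literal["first", "second"] = "first"
                    ) -> Tuple[float, float]:
    """Standardise the direction of a pair of estimates.

    Both values are multiplied by -1 iff the anchoring method's estimate
    is strictly negative (an anchor of exactly 0 leaves the pair
    unchanged).  ``anchor='second'`` is the sensitivity variant.
    """
    ref = a if anchor == "first" else b
    if ref < 0:
        return (-a, -b)
    return (a, b)


# ---------------------------------------------------------------------------
# Bland-Altman


@dataclass(frozen=True)
class AgreementSummary:
    """Mean difference and 95% limits of agreement (mean ± 1.96 sd).

    For log-scale (standard error) comparisons the multiplicative
    re-expression is attached: geometric mean ratio exp(mean) with
    multiplicative limits exp(loa).
    """

    mean_difference: float
    loa_low: float
    loa_high: float
    n_pairs: int
    log_scale: bool = False
    geometric_mean_ratio: Optional[float] = None
    gmr_loa_low: Optional[float] = None
    gmr_loa_high: Optional[float] = None


def bland_altman(x: Sequence[float], y: Sequence[float], log_scale: bool = False
                 ) -> Tuple[AgreementSummary, pd.DataFrame]:
    """Bland-Altman agreement between two paired sets of values.

    Differences are x - y (log x - log y when ``log_scale``), averages
    (x + y)/2 (mean of logs).  The sd of differences uses the n-1
    divisor.  Non-positive pairs under ``log_scale`` are dropped (the
    returned table records only retained pairs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ComparisonError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    if log_scale:
        keep &= (x > 0) & (y > 0)
    x, y = x[keep], y[keep]
    if len(x) < 2:
        raise ComparisonError(f"need at least 2 usable pairs, got {len(x)}")
    if log_scale:
        xv, yv = np.log(x), np.log(y)
    else:
        xv, yv = x, y
    diff = xv - yv
    avg = (xv + yv) / 2.0
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    loa = (mean - 1.96 * sd, mean + 1.96 * sd)
    table = pd.DataFrame({"difference": diff, "average": avg})
    summary = AgreementSummary(
        mean_difference=mean, loa_low=loa[0], loa_high=loa[1],
        n_pairs=len(x), log_scale=log_scale,
        geometric_mean_ratio=float(np.exp(mean)) if log_scale else None,
        gmr_loa_low=float(np.exp(loa[0])) if log_scale else None,
        gmr_loa_high=float(np.exp(loa[1])) if log_scale else None,
    )
    return summary, table


# ---------------------------------------------------------------------------
# CI width comparison


@dataclass(frozen=True)
class CIWidthComparison:
    """One pairwise CI comparison on the reference [-0.5, 0.5] scale."""

    scaled_other: Tuple[float, float]
    scaled_ref_point: float
    scaled_other_point: float
    width_ratio: float
    other_wider: bool
    ref_point_outside_other: bool
    other_point_outside_ref: bool


def ci_width_comparison(ci_ref: Tuple[float, float], ci_other: Tuple[float, float],
                        point_ref: float, point_other: float) -> CIWidthComparison:
    """Scale both intervals so the reference CI spans (-0.5, 0.5).

    The affine map x -> (x - centre_ref) / width_ref is applied to the
    other method's CI and to both point estimates.  The width ratio and
    the mutual point-containment flags are invariant under any common
    affine transformation of the inputs.
    """
    lo_r, hi_r = float(ci_ref[0]), float(ci_ref[1])
    lo_o, hi_o = float(ci_other[0]), float(ci_other[1])
    if not (lo_r < hi_r) or not (lo_o < hi_o):
        raise ComparisonError("both confidence intervals must have positive width")
    width = hi_r - lo_r
    centre = (hi_r + lo_r) / 2.0

    def scale(v: float) -> float:
        return (v - centre) / width

    ratio = (hi_o - lo_o) / width
    return CIWidthComparison(
        scaled_other=(scale(lo_o), scale(hi_o)),
        scaled_ref_point=scale(point_ref),
        scaled_other_point=scale(point_other),
        width_ratio=float(ratio),
        other_wider=bool(ratio > 1.0),
        ref_point_outside_other=bool(point_ref < lo_o or point_ref > hi_o),
        other_point_outside_ref=bool(point_other < lo_r or point_other > hi_r),
    )


# ---------------------------------------------------------------------------
# p-value categorisation and concordance

FINE_LABELS = ("p<=0.01", "0.01<p<=0.05", "0.05<p<=0.10", "p>0.10")


def categorize_p(p: float, scheme: Literal["binary", "fine"] = "binary",
                 strict_less: bool = False) -> str:
    """Categorise a p-value at the 5% level or on the finer gradation.

    The default boundary convention counts p = 0.05 as significant
    (p <= 0.05); ``strict_less=True`` switches to the strict-inequality
    reading.  The fine scheme uses boundaries 0.01, 0.05, 0.10 with the
    same membership convention.
    """
    if not (0.0 <= p <= 1.0):
        raise ComparisonError(f"p-value {p} outside [0, 1]")
    bounds = (0.01, 0.05, 0.10)
    if strict_less:
        k = int(np.searchsorted(bounds, p, side="right"))
    else:
        k = int(np.searchsorted(bounds, p, side="left"))
    if scheme == "binary":
        return "significant" if k <= 1 else "not significant"
    if scheme == "fine":
        return FINE_LABELS[k]
    raise ComparisonError(f"unknown scheme {scheme!r}")


def kappa_adjective(kappa: float) -> str:
    """Interpretation band for a kappa value."""
    if kappa > 0.80:
        return "almost perfect"
    if kappa > 0.60:
        return "substantial"
    if kappa > 0.40:
        return "moderate"
    if kappa > 0.20:
        return "fair"
    if kappa > 0.0:
        return "slight"
    return "poor"


@dataclass(frozen=True)
class ConcordanceTable:
    """Contingency table with percent agreement and unweighted kappa."""

    labels: Tuple[str, ...]
    counts: np.ndarray  # square, rows = a, cols = b
    percent_agreement: float
    kappa: float
    kappa_band: str
    n_pairs: int


def concordance(categories_a: Sequence[str], categories_b: Sequence[str],
                labels: Optional[Sequence[str]] = None) -> ConcordanceTable:
    """Percent agreement and unweighted Cohen's kappa for paired categories.

    kappa = (p_o - p_e) / (1 - p_e) with the chance term p_e from the
    products of the marginal proportions.  When both raters agree on
    every item and use a single category, kappa is reported as 1.
    """
    a = list(categories_a)
    b = list(categories_b)
    if len(a) != len(b):
        raise ComparisonError("category vectors must have equal length")
    if len(a) == 0:
        raise ComparisonError("empty category vectors")
    if labels is None:
        labels = sorted(set(a) | set(b))
    labels = tuple(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=int)
    for ai, bi in zip(a, b):
        counts[index[ai], index[bi]] += 1
    n = counts.sum()
    p_o = float(np.trace(counts)) / n
    row = counts.sum(axis=1) / n
    col = counts.sum(axis=0) / n
    p_e = float(row @ col)
    if p_e >= 1.0:
        kap = 1.0 if p_o >= 1.0 else 0.0
    else:
        kap = (p_o - p_e) / (1.0 - p_e)
    return ConcordanceTable(
        labels=labels, counts=counts,
        percent_agreement=100.0 * p_o, kappa=float(kap),
        kappa_band=kappa_adjective(float(kap)), n_pairs=int(n),
    )


# ---------------------------------------------------------------------------
# autocorrelation summaries


def autocorrelation_summary(estimates: pd.DataFrame) -> pd.DataFrame:
    """Stratified medians and IQRs of autocorrelation estimates.

    ``estimates`` must have columns ``method``, ``series_id``,
    ``rho_hat``, ``series_length`` and ``valid`` (only valid rows are
    summarised; upstream validity already encodes the |rho| >= 1
    exclusions).  Strata: all series, series with >= 24 points, series
    with >= 100 points, and the common-support subset of series where
    every method present produced a valid estimate.  Empty strata are
    reported with n = 0.
    """
    req = {"method", "series_id", "rho_hat", "series_length", "valid"}
    missing = req - set(estimates.columns)
    if missing:
        raise ComparisonError(f"estimates table missing columns {sorted(missing)}")
    df = estimates[estimates["valid"] & np.isfinite(estimates["rho_hat"])].copy()
    methods = sorted(df["method"].unique())
    if methods:
        per_series = df.groupby("series_id")["method"].nunique()
        common_ids = set(per_series[per_series == len(methods)].index)
    else:
        common_ids = set()

    strata = {
        "all": lambda d: d,
        ">=24": lambda d: d[d["series_length"] >= 24],
        ">=100": lambda d: d[d["series_length"] >= 100],
        "common": lambda d: d[d["series_id"].isin(common_ids)],
    }
    rows = []
    for method in methods:
        sub = df[df["method"] == method]
        for name, fn in strata.items():
            s = fn(sub)["rho_hat"]
            if len(s):
                q1, med, q3 = np.percentile(s, [25, 50, 75])
            else:
                q1 = med = q3 = np.nan
            rows.append({"method": method, "stratum": name, "n": len(s),
                         "median": med, "q1": q1, "q3": q3})
    return pd.DataFrame(rows, columns=["method", "stratum", "n", "median", "q1", "q3"])
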