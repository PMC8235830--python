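"""Batch driver: fit every method on every series and compare them.

Reproduces the study design on an arbitrary collection: each series is
fitted with all configured estimators (failures and boundary
autocorrelation estimates are recorded in an exclusion ledger, never
aborting the batch), and every pairwise comparison from the analysis
plan is computed — Bland-Altman agreement of standardised level/slope
changes and of log standard errors, CI-width comparisons, significance
concordance at the 5% level and on the finer gradation, and stratified
autocorrelation summaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .comparison import (align_direction, autocorrelation_summary, bland_altman,
                         categorize_p, ci_width_comparison, concordance,
                         standardize_fit)
from .datasets import DatasetError, TimeSeriesDataset, read_series_file
from .design import DesignError, build_design
from .estimators import METHODS, EstimationError, FitResult, fit_method
from .simulate import CollectionParams, simulate_collection

__all__ = ["RunConfig", "ComparisonReport", "run_series", "run_collection",
           "write_report", "read_fit_table", "load_config"]

REASON_CODES = ("nonconvergence", "rho_out_of_bounds", "rank_deficient",
                "zero_rmse", "io_error")

# Autocorrelation is a model parameter for these methods only.
RHO_METHODS = ("PW", "REML", "ARIMA")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration.

    Either ``input_dir`` (a directory of series files) or ``synthetic``
    (collection parameters) must be set.  ``significance_strict_less``
    selects the p < 0.05 boundary convention instead of the default
    p <= 0.05; ``direction_anchor`` chooses which method of a pair
    anchors the sign standardisation.
    """

    input_dir: Optional[str] = None
    synthetic: Optional[CollectionParams] = CollectionParams()
    methods: Tuple[str, ...] = METHODS
    significance_strict_less: bool = False
    direction_anchor: str = "first"
    satterthwaite_floor: float = 2.0
    seed: int = 0
    output_dir: str = "itscompare_report"

    def __post_init__(self) -> None:
        if len(self.methods) < 2:
            raise ConfigError("need at least two methods to compare")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ConfigError(f"unknown methods {sorted(unknown)}")
        if self.satterthwaite_floor < 1:
            raise ConfigError("satterthwaite_floor must be >= 1")
        if self.direction_anchor not in ("first", "second"):
            raise ConfigError("direction_anchor must be 'first' or 'second'")
        if self.input_dir is None and self.synthetic is None:
            raise ConfigError("either input_dir or synthetic parameters required")


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML mapping."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "synthetic" in raw and isinstance(raw["synthetic"], dict):
        syn = dict(raw["synthetic"])
        for key in ("length_range", "pre_fraction_range", "rho_beta", "rho_range"):
            if key in syn:
                syn[key] = tuple(syn[key])
        raw["synthetic"] = CollectionParams(**syn)
    if "methods" in raw:
        raw["methods"] = tuple(raw["methods"])
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


@dataclass
class ComparisonReport:
    """Everything the batch run produces, as plain tables."""

    fits: pd.DataFrame           # per series/method/coefficient-role rows
    exclusions: pd.DataFrame     # series_id, method, reason, detail
    standardized: pd.DataFrame   # per series/method standardised effects
    agreement: pd.DataFrame      # pairwise Bland-Altman summaries
    ci_widths: pd.DataFrame      # per series/pair CI width comparisons
    significance: pd.DataFrame   # pairwise percent agreement + kappa
    autocorrelation: pd.DataFrame
    rho_estimates: pd.DataFrame  # per-series rho with CIs (scatter/CI analogue)
    n_series: int = 0

    def pair_denominators(self) -> pd.DataFrame:
        """Valid-pair counts per method pair (study Table-4 analogue)."""
        return (self.agreement[self.agreement["quantity"] == "level_change"]
                [["method_a", "method_b", "n_pairs"]].reset_index(drop=True))


def run_series(dataset: TimeSeriesDataset, config: RunConfig
               ) -> Tuple[Dict[str, FitResult], List[dict]]:
    """Fit all configured methods on one series.

    Returns the per-method results plus exclusion-ledger entries; a fit
    appears in exactly one of the two.  Exclusion reasons are machine
    readable: nonconvergence, rho_out_of_bounds, rank_deficient,
    zero_rmse.
    """
    fits: Dict[str, FitResult] = {}
    ledger: List[dict] = []
    try:
        design = build_design(dataset)
    except DesignError as exc:
        for m in config.methods:
            ledger.append({"series_id": dataset.series_id, "method": m,
                           "reason": "rank_deficient", "detail": str(exc)})
        return fits, ledger

    for m in config.methods:
        try:
            kwargs = {}
            if m == "REML-Satt":
                kwargs["df_floor"] = config.satterthwaite_floor
            fit = fit_method(m, design, dataset.y, **kwargs)
        except (EstimationError, np.linalg.LinAlgError) as exc:
            ledger.append({"series_id": dataset.series_id, "method": m,
                           "reason": "nonconvergence", "detail": str(exc)})
            continue
        if not fit.valid:
            ledger.append({"series_id": dataset.series_id, "method": m,
                           "reason": "rho_out_of_bounds",
                           "detail": f"rho_hat={fit.rho_hat}"})
        elif not fit.converged or not np.all(np.isfinite(fit.se)):
            ledger.append({"series_id": dataset.series_id, "method": m,
                           "reason": "nonconvergence",
                           "detail": "optimiser or SE failure"})
        elif fit.degenerate:
            ledger.append({"series_id": dataset.series_id, "method": m,
                           "reason": "zero_rmse", "detail": "zero residual variance"})
        else:
            fits[m] = fit
    return fits, ledger


def _collect_datasets(config: RunConfig) -> Tuple[List[TimeSeriesDataset], List[dict]]:
    ledger: List[dict] = []
    if config.input_dir is not None:
        datasets = []
        for path in sorted(Path(config.input_dir).glob("*.csv")):
            if path.name == "manifest.csv":
                continue
            try:
                datasets.append(read_series_file(path))
            except DatasetError as exc:
                ledger.append({"series_id": path.stem, "method": "*",
                               "reason": "io_error", "detail": str(exc)})
        return datasets, ledger
    datasets, _ = simulate_collection(config.synthetic)
    return datasets, ledger


def _fit_rows(series_id: str, fit: FitResult, design) -> List[dict]:
    rows = []
    for role, idx in sorted(design.roles.items(), key=lambda kv: kv[1]):
        rows.append({
            "series_id": series_id, "method": fit.method, "role": role,
            "estimate": fit.beta[idx], "se": fit.se[idx], "df": fit.df[idx],
            "ci_low": fit.ci[idx, 0], "ci_high": fit.ci[idx, 1],
            "p": fit.p[idx], "rho_hat": fit.rho_hat if fit.rho_hat is not None else np.nan,
            "valid": fit.valid, "converged": fit.converged,
            "series_length": design.n,
        })
    return rows


def run_collection(config: RunConfig) -> ComparisonReport:
    """End-to-end batch: fit, exclude, standardise, compare, summarise."""
    datasets, ledger = _collect_datasets(config)
    methods = list(config.methods)

    fit_rows: List[dict] = []
    std_rows: List[dict] = []
    rho_rows: List[dict] = []
    per_series: Dict[str, Dict[str, FitResult]] = {}
    designs: Dict[str, object] = {}
    lengths: Dict[str, int] = {}

    for ds in datasets:
        fits, entries = run_series(ds, config)
        ledger.extend(entries)
        if not fits:
            continue
        design = build_design(ds)
        per_series[ds.series_id] = fits
        designs[ds.series_id] = design
        lengths[ds.series_id] = ds.n
        ols_rmse = fits["OLS"].rmse if "OLS" in fits else None
        for m, fit in fits.items():
            fit_rows.extend(_fit_rows(ds.series_id, fit, design))
            if fit.rho_hat is not None and m in RHO_METHODS:
                lo, hi = fit.rho_ci if fit.rho_ci else (np.nan, np.nan)
                rho_rows.append({
                    "series_id": ds.series_id, "method": m, "rho_hat": fit.rho_hat,
                    "rho_ci_low": lo, "rho_ci_high": hi,
                    "series_length": ds.n, "valid": fit.valid,
                    "ci_excludes_zero": bool(np.isfinite(lo) and (lo > 0 or hi < 0)),
                })
            if ols_rmse and ols_rmse > 0:
                s = standardize_fit(fit, ols_rmse, design)
                std_rows.append({
                    "series_id": ds.series_id, "method": m,
                    "level_change": s.level_change, "slope_change": s.slope_change,
                    "level_se": s.level_se, "slope_se": s.slope_se,
                    "level_ci_low": s.level_ci[0], "level_ci_high": s.level_ci[1],
                    "slope_ci_low": s.slope_ci[0], "slope_ci_high": s.slope_ci[1],
                    "level_p": s.level_p, "slope_p": s.slope_p,
                    "series_length": ds.n,
                })

    fits_df = pd.DataFrame(fit_rows, columns=[
        "series_id", "method", "role", "estimate", "se", "df", "ci_low",
        "ci_high", "p", "rho_hat", "valid", "converged", "series_length"])
    std_df = pd.DataFrame(std_rows, columns=[
        "series_id", "method", "level_change", "slope_change", "level_se",
        "slope_se", "level_ci_low", "level_ci_high", "slope_ci_low",
        "slope_ci_high", "level_p", "slope_p", "series_length"])
    ledger_df = pd.DataFrame(ledger, columns=["series_id", "method", "reason", "detail"])
    rho_df = pd.DataFrame(rho_rows, columns=[
        "series_id", "method", "rho_hat", "rho_ci_low", "rho_ci_high",
        "series_length", "valid", "ci_excludes_zero"])

    agreement_rows: List[dict] = []
    ci_rows: List[dict] = []
    signif_rows: List[dict] = []

    idx = std_df.set_index(["series_id", "method"]) if len(std_df) else None
    for ma, mb in itertools.combinations(methods, 2):
        if idx is None:
            continue
        common = [sid for sid, f in per_series.items() if ma in f and mb in f
                  and (sid, ma) in idx.index and (sid, mb) in idx.index]
        common.sort()
        if len(common) < 2:
            continue
        a = idx.loc[[(sid, ma) for sid in common]].reset_index()
        b = idx.loc[[(sid, mb) for sid in common]].reset_index()

        for effect in ("level_change", "slope_change"):
            av, bv = [], []
            for x, yv in zip(a[effect], b[effect]):
                x2, y2 = align_direction(float(x), float(yv), config.direction_anchor)
                av.append(x2)
                bv.append(y2)
            summ, _ = bland_altman(av, bv, log_scale=False)
            agreement_rows.append({
                "method_a": ma, "method_b": mb, "quantity": effect,
                "mean_difference": summ.mean_difference,
                "loa_low": summ.loa_low, "loa_high": summ.loa_high,
                "geometric_mean_ratio": np.nan, "n_pairs": summ.n_pairs})
            se_col = "level_se" if effect == "level_change" else "slope_se"
            try:
                # SE ratios reported as column/row (comparator over reference)
                summ_se, _ = bland_altman(b[se_col], a[se_col], log_scale=True)
                agreement_rows.append({
                    "method_a": ma, "method_b": mb, "quantity": f"log_se_{effect}",
                    "mean_difference": summ_se.mean_difference,
                    "loa_low": summ_se.loa_low, "loa_high": summ_se.loa_high,
                    "geometric_mean_ratio": summ_se.geometric_mean_ratio,
                    "n_pairs": summ_se.n_pairs})
            except Exception:
                pass

            lo_c = "level_ci_low" if effect == "level_change" else "slope_ci_low"
            hi_c = "level_ci_high" if effect == "level_change" else "slope_ci_high"
            pt_c = effect
            for i, sid in enumerate(common):
                ref = (float(a[lo_c][i]), float(a[hi_c][i]))
                oth = (float(b[lo_c][i]), float(b[hi_c][i]))
                if not (ref[0] < ref[1]) or not (oth[0] < oth[1]):
                    continue
                cw = ci_width_comparison(ref, oth, float(a[pt_c][i]), float(b[pt_c][i]))
                ci_rows.append({
                    "series_id": sid, "method_ref": ma, "method_other": mb,
                    "quantity": effect, "width_ratio": cw.width_ratio,
                    "other_wider": cw.other_wider,
                    "scaled_other_low": cw.scaled_other[0],
                    "scaled_other_high": cw.scaled_other[1],
                    "ref_point_outside_other": cw.ref_point_outside_other,
                    "other_point_outside_ref": cw.other_point_outside_ref})

            p_col = "level_p" if effect == "level_change" else "slope_p"
            for scheme in ("binary", "fine"):
                cats_a = [categorize_p(float(p), scheme,
                                       config.significance_strict_less)
                          for p in a[p_col]]
                cats_b = [categorize_p(float(p), scheme,
                                       config.significance_strict_less)
                          for p in b[p_col]]
                tab = concordance(cats_a, cats_b)
                signif_rows.append({
                    "method_a": ma, "method_b": mb, "quantity": effect,
                    "scheme": scheme,
                    "percent_agreement": tab.percent_agreement,
                    "kappa": tab.kappa if scheme == "binary" else np.nan,
                    "kappa_band": tab.kappa_band if scheme == "binary" else "",
                    "n_pairs": tab.n_pairs})

    autocorr_df = (autocorrelation_summary(rho_df) if len(rho_df)
                   else pd.DataFrame(columns=["method", "stratum", "n",
                                              "median", "q1", "q3"]))

    return ComparisonReport(
        fits=fits_df,
        exclusions=ledger_df,
        standardized=std_df,
        agreement=pd.DataFrame(agreement_rows, columns=[
            "method_a", "method_b", "quantity", "mean_difference", "loa_low",
            "loa_high", "geometric_mean_ratio", "n_pairs"]),
        ci_widths=pd.DataFrame(ci_rows, columns=[
            "series_id", "method_ref", "method_other", "quantity",
            "width_ratio", "other_wider", "scaled_other_low",
            "scaled_other_high", "ref_point_outside_other",
            "other_point_outside_ref"]),
        significance=pd.DataFrame(signif_rows, columns=[
            "method_a", "method_b", "quantity", "scheme",
            "percent_agreement", "kappa", "kappa_band", "n_pairs"]),
        autocorrelation=autocorr_df,
        rho_estimates=rho_df,
        n_series=len(datasets),
    )


_REPORT_FILES = {
    "fits": "fits.csv",
    "exclusions": "exclusions.csv",
    "standardized": "standardized_estimates.csv",
    "agreement": "agreement_summary.csv",
    "ci_widths": "ci_width_comparison.csv",
    "significance": "significance_agreement.csv",
    "autocorrelation": "autocorrelation_summary.csv",
    "rho_estimates": "autocorrelation_estimates.csv",
}


def write_report(report: ComparisonReport, outdir: str | Path) -> None:
    """Write every report table as delimited text (full float precision)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, fname in _REPORT_FILES.items():
        getattr(report, attr).to_csv(outdir / fname, index=False)
    (outdir / "n_series.txt").write_text(f"{report.n_series}\n")


def read_fit_table(path: str | Path) -> pd.DataFrame:
    """Read back a fits.csv written by :func:`write_report`."""
    return pd.read_csv(path)
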