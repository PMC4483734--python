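"""Exposure-response curves, MMT location and percentile relative-risk tables.

A fitted DLNM is summarised by the cumulative (over lags) exposure-response
curve RR(T) = exp(contrast(T, ref)' beta), centered so RR(ref) = 1.  Pointwise
standard errors come from the delta method, se(T)^2 = v' V v with v the
contrast vector and V the dispersion-scaled coefficient covariance, and 95%
intervals are Wald on the log scale: exp(log RR ± 1.96 se).

The minimum mortality temperature (MMT) is the grid argmin of the cumulative
curve inside a percentile window (10th-90th by default, keeping the search
away from variance-inflated spline tails), and relative risks are reported at
the 1st/5th/95th/99th percentile temperatures of the analysed series,
re-centered at each category's MMT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .crossbasis import CrossBasis, build_crossbasis, contrast_matrix
from .data_io import MortalityTimeSeries, derive_calendar_covariates
from .glm import FitResult, assemble_design, fit_quasipoisson

__all__ = [
    "ExposureResponseCurve",
    "predict_curve",
    "find_mmt",
    "rr_at_percentiles",
    "run_category_analysis",
    "default_grid",
]


@dataclass
class ExposureResponseCurve:
    """RR(temperature) with pointwise 95% CIs, centered at ``ref_temp``."""

    grid: np.ndarray
    log_rr: np.ndarray
    se: np.ndarray
    ref_temp: float
    ci_z: float = 1.96
    mmt: float | None = None
    mode: str = "cumulative"
    lag: int | None = None

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.log_rr - self.ci_z * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.log_rr + self.ci_z * self.se)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "temp": self.grid,
            "rr": self.rr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "log_rr": self.log_rr,
            "se": self.se,
        })


def default_grid(tmean, step: float = 0.1) -> np.ndarray:
    """Uniform temperature grid over the observed range (inclusive)."""
    lo, hi = float(np.min(tmean)), float(np.max(tmean))
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def predict_curve(
    fit: FitResult,
    cb: CrossBasis,
    grid,
    ref: float,
    mode: str = "cumulative",
    lag: int | None = None,
    ci_z: float = 1.96,
) -> ExposureResponseCurve:
    """Delta-method exposure-response curve from a fitted model.

    ``log_rr(T) = contrast(T, ref)' beta_cb`` and
    ``se(T) = sqrt(contrast' V_cb contrast)`` restricted to the cross-basis
    coefficient block.  Grid points beyond the predictor-basis boundary are
    flagged with an extrapolation warning.
    """
    grid = np.asarray(grid, float)
    if cb.pred_spec.kind == "ncs":
        lo, hi = cb.pred_spec.boundary
        n_out = int(np.sum((grid < lo) | (grid > hi)))
        if n_out:
            warnings.warn(
                f"{n_out} grid point(s) outside basis boundary [{lo:.2f}, {hi:.2f}]: "
                "extrapolating linear tails",
                stacklevel=2,
            )
    Cmat = contrast_matrix(cb.pred_spec, cb.lag_spec, cb.max_lag, grid, ref, mode, lag)
    beta = fit.block_params("crossbasis")
    V = fit.block_cov("crossbasis")
    log_rr = Cmat @ beta
    var = np.einsum("ij,jk,ik->i", Cmat, V, Cmat)
    se = np.sqrt(np.maximum(var, 0.0))
    return ExposureResponseCurve(grid, log_rr, se, float(ref), ci_z, mode=mode, lag=lag)


def find_mmt(
    curve: ExposureResponseCurve,
    t_lo: float | None = None,
    t_hi: float | None = None,
    flat_tol: float = 0.0,
) -> float:
    """Grid argmin of the cumulative log-RR within [t_lo, t_hi].

    Ties break toward the lowest temperature.  A flat curve triggers a
    warning and returns the midpoint of the search range.
    """
    mask = np.ones(len(curve.grid), bool)
    if t_lo is not None:
        mask &= curve.grid >= t_lo
    if t_hi is not None:
        mask &= curve.grid <= t_hi
    if not mask.any():
        raise ValueError("empty MMT search range")
    g, y = curve.grid[mask], curve.log_rr[mask]
    if np.ptp(y) <= flat_tol:
        warnings.warn("flat exposure-response curve; MMT set to range midpoint", stacklevel=2)
        mmt = float(0.5 * (g[0] + g[-1]))
    else:
        mmt = float(g[int(np.argmin(y))])  # argmin takes the first (lowest T) on ties
    curve.mmt = mmt
    return mmt


def rr_at_percentiles(
    curve: ExposureResponseCurve,
    series: MortalityTimeSeries,
    percentiles=(1, 5, 95, 99),
    category: str = "all",
) -> pd.DataFrame:
    """Table-2-style rows: RR and CI at percentile temperatures of the series.

    Percentile temperatures use the fixed type-7 rule; RR and CI bounds are
    interpolated linearly between grid points.
    """
    temps = np.percentile(series.tmean, percentiles)
    grid = curve.grid
    rows = []
    for p, t in zip(percentiles, temps):
        rows.append({
            "category": category,
            "percentile": p,
            "temp": float(t),
            "rr": float(np.interp(t, grid, curve.rr)),
            "ci_low": float(np.interp(t, grid, curve.ci_low)),
            "ci_high": float(np.interp(t, grid, curve.ci_high)),
            "mmt": curve.mmt,
        })
    return pd.DataFrame(rows)


def run_category_analysis(
    series: MortalityTimeSeries,
    categories=None,
    config: AnalysisConfig | None = None,
):
    """Full per-category pipeline: cross-basis -> quasi-Poisson fit -> MMT ->
    percentile RR rows, sharing one exposure cross-basis and design.

    Returns ``(rr_table, curves, fits)`` where ``rr_table`` mirrors the
    category × {1st, 5th, 95th, 99th percentile, MMT} report layout.
    """
    from .basis import default_knots  # local to avoid cycle at import time

    config = config or AnalysisConfig()
    categories = list(categories) if categories is not None else series.categories
    if not categories:
        raise ValueError("empty category list")
    missing = [c for c in categories if c not in series.categories]
    if missing:
        raise ValueError(f"unknown categories: {missing}")

    from .crossbasis import make_lag_spec

    pred_spec = default_knots(series.tmean, config.pred_df)
    lag_spec = make_lag_spec(config.lag_df, config.max_lag)
    cb = build_crossbasis(series.tmean, pred_spec, lag_spec, config.max_lag)
    cov = derive_calendar_covariates(series, config.holidays)
    X, names, slices, rows = assemble_design(series, cb, cov, config)
    grid = default_grid(series.tmean, config.grid_step)
    w_lo, w_hi = np.percentile(series.tmean, config.mmt_window)

    tables, curves, fits = [], {}, {}
    for cat in categories:
        y = series.deaths[cat].to_numpy()[rows]
        if not y.any():
            warnings.warn(f"category '{cat}' has all-zero counts: skipped", stacklevel=2)
            continue
        fit = fit_quasipoisson(y, X, names, slices)
        provisional = predict_curve(fit, cb, grid, ref=float(np.median(series.tmean)),
                                    ci_z=config.ci_z)
        mmt = find_mmt(provisional, w_lo, w_hi)
        curve = predict_curve(fit, cb, grid, ref=mmt, ci_z=config.ci_z)
        curve.mmt = mmt
        tables.append(rr_at_percentiles(curve, series, config.percentiles, cat))
        curves[cat] = curve
        fits[cat] = fit
    if not tables:
        raise ValueError("no category produced a fit (all zero?)")
    return pd.concat(tables, ignore_index=True), curves, fits
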