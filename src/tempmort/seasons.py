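"""Season-specific analysis on log-transformed mortality.

Stacking the same calendar season from successive years does not produce one
continuous daily series, so the season-specific model abandons the Poisson
time-series formulation.  Instead, for each PAGASA season the response is the
log-transformed count, log(Y + 1), modelled by ordinary least squares:

    log(Y_season + 1) = alpha + beta_season' T_season,l + ns(doy, 4)
                        + ns(time_within_season, 3) + ns(rh, 3)
                        + dow dummies + holiday

The lagged-exposure block T_season,l is computed on the FULL continuous
series before subsetting to the season's rows, so no lag history is
fabricated across season boundaries.  Effect curves are exponentiated
contrasts (an RR-analogue on the log-count scale) with delta-method CIs from
the classical Gaussian covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .basis import default_knots, ncs_basis
from .config import AnalysisConfig
from .crossbasis import CrossBasis, build_crossbasis, make_lag_spec
from .data_io import SEASONS, MortalityTimeSeries, derive_calendar_covariates
from .effects import ExposureResponseCurve, default_grid, predict_curve
from .glm import RankDeficiencyError, _collinear_columns

__all__ = [
    "SeasonSubset",
    "SeasonFit",
    "split_by_season",
    "fit_season_model",
    "season_rr",
    "season_slope",
    "run_season_analysis",
]


@dataclass
class SeasonSubset:
    """Rows of the parent series belonging to one season."""

    season: str
    rows: np.ndarray          # indices into the full series
    dates: pd.DatetimeIndex
    within_season_time: np.ndarray  # 0, 1, 2, ... over the season's stacked days


@dataclass
class SeasonFit:
    """Gaussian fit of one season's log-mortality model."""

    season: str
    params: np.ndarray
    cov: np.ndarray
    sigma2: float
    df_residual: int
    n_obs: int
    column_names: list
    block_slices: dict = field(default_factory=dict)
    category: str = "all"
    log_offset: float = 1.0

    def block_params(self, name):
        return self.params[self.block_slices[name]]

    def block_cov(self, name):
        s = self.block_slices[name]
        return self.cov[s, :][:, s]


def split_by_season(series: MortalityTimeSeries, min_days: int = 60) -> dict:
    """Partition the series rows by PAGASA season.

    Every row lands in exactly one subset; each subset keeps its original
    dates plus a within-season time index.  A season with fewer than
    ``min_days`` rows is insufficient for the seasonal model and raises.
    """
    labels = series.season
    out = {}
    for s in SEASONS:
        rows = np.flatnonzero(labels == s)
        if len(rows) < min_days:
            raise ValueError(
                f"season {s} has only {len(rows)} day(s); need >= {min_days}"
            )
        out[s] = SeasonSubset(
            season=s,
            rows=rows,
            dates=series.dates[rows],
            within_season_time=np.arange(len(rows)),
        )
    return out


def _season_design(series, sub, cb, config):
    """Design for one season: cross-basis rows (lags from the full series) +
    within-season calendar splines + humidity spline + dow + holiday."""
    usable = np.intersect1d(sub.rows, cb.usable_rows)
    cb_rows = np.searchsorted(cb.usable_rows, usable)
    sub_pos = np.searchsorted(sub.rows, usable)

    cov = derive_calendar_covariates(series, config.holidays)
    doy = cov.doy[usable].astype(float)
    wtime = sub.within_season_time[sub_pos].astype(float)
    rh = series.rh[usable]

    blocks = [("intercept", np.ones((len(usable), 1)), ["intercept"])]
    cb_names = [f"cb_{j}_{k}" for j, k in cb.column_index]
    blocks.append(("crossbasis", cb.matrix[cb_rows], cb_names))
    # DJF wraps the year end: use days since Dec 1 so doy is smooth in-season
    if sub.season == "DJF":
        doy = np.where(doy >= 335, doy - 335, doy + 31)
    doy_spec = default_knots(doy, 4)
    blocks.append(("doy", ncs_basis(doy, doy_spec), [f"doy_{i}" for i in range(4)]))
    time_spec = default_knots(wtime, 3, equally_spaced=True)
    blocks.append(("time", ncs_basis(wtime, time_spec), [f"time_{i}" for i in range(3)]))
    if np.ptp(rh) > 0:
        rh_spec = default_knots(rh, config.rh_df)
        blocks.append(("rh", ncs_basis(rh, rh_spec),
                       [f"rh_{i}" for i in range(config.rh_df)]))
    dow = cov.dow[usable]
    blocks.append(("dow", np.column_stack([(dow == d).astype(float) for d in range(1, 7)]),
                   [f"dow_{d}" for d in range(1, 7)]))
    hod = cov.hod[usable].astype(float)
    if hod.any():
        blocks.append(("hod", hod[:, None], ["hod"]))

    X = np.hstack([b for _, b, _ in blocks])
    names, slices, start = [], {}, 0
    for name, mat, colnames in blocks:
        slices[name] = slice(start, start + mat.shape[1])
        names.extend(colnames)
        start += mat.shape[1]
    return X, names, slices, usable


def fit_season_model(
    series: MortalityTimeSeries,
    sub: SeasonSubset,
    cb: CrossBasis,
    config: AnalysisConfig | None = None,
    category: str = "all",
) -> SeasonFit:
    """OLS of log(deaths + offset) on the season's design.

    ``cb`` must be built on the full series exposure so that lag histories
    cross season boundaries correctly.
    """
    config = config or AnalysisConfig()
    X, names, slices, usable = _season_design(series, sub, cb, config)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(
            f"season design rank deficient; collinear: {_collinear_columns(X, names)}"
        )
    y = np.log(series.deaths[category].to_numpy()[usable] + config.season_log_offset)
    res = sm.OLS(y, X).fit()
    return SeasonFit(
        season=sub.season,
        params=np.asarray(res.params, float),
        cov=np.asarray(res.cov_params(), float),
        sigma2=float(res.mse_resid),
        df_residual=int(res.df_resid),
        n_obs=len(y),
        column_names=names,
        block_slices=slices,
        category=category,
        log_offset=config.season_log_offset,
    )


def season_rr(fit: SeasonFit, cb: CrossBasis, grid, ref: float,
              ci_z: float = 1.96) -> ExposureResponseCurve:
    """Exponentiated-contrast effect curve for a season fit (RR-analogue on
    the log-count scale), centered at ``ref``."""
    return predict_curve(fit, cb, grid, ref, ci_z=ci_z)


def season_slope(fit: SeasonFit, cb: CrossBasis, t1: float, t2: float,
                 ci_z: float = 1.96) -> dict:
    """Cumulative per-°C effect between two temperatures, with Wald CI.

    With a linear or threshold predictor basis this is the season's slope;
    with a spline basis it is the average slope over [t1, t2].
    """
    if not t2 > t1:
        raise ValueError("require t2 > t1")
    from .crossbasis import crossbasis_contrast

    v = crossbasis_contrast(cb.pred_spec, cb.lag_spec, cb.max_lag, t2, t1) / (t2 - t1)
    beta = fit.block_params("crossbasis")
    V = fit.block_cov("crossbasis")
    slope = float(v @ beta)
    se = float(np.sqrt(max(v @ V @ v, 0.0)))
    return {"slope": slope, "se": se,
            "ci_low": slope - ci_z * se, "ci_high": slope + ci_z * se}


def run_season_analysis(
    series: MortalityTimeSeries,
    config: AnalysisConfig | None = None,
    category: str = "all",
    slope_temps: tuple | None = None,
) -> dict:
    """Fit all four season models sharing one full-series cross-basis.

    Returns season -> {fit, curve, slope}.  ``slope_temps`` defaults to the
    full-series median and 99th-percentile temperatures, so the reported
    slope is the average heat-side effect per °C.
    """
    config = config or AnalysisConfig()
    if config.season_pred == "ncs":
        pred_spec = default_knots(series.tmean, config.pred_df)
    elif config.season_pred == "sthr":
        from .basis import BasisSpec

        high = (config.season_sthr_threshold
                if config.season_sthr_threshold is not None
                else float(np.percentile(series.tmean, 75)))
        pred_spec = BasisSpec(kind="sthr", thresholds=(high,))
    elif config.season_pred == "linear":
        from .basis import BasisSpec

        pred_spec = BasisSpec(kind="linear")
    else:
        raise ValueError(f"unknown season_pred '{config.season_pred}'")
    lag_spec = make_lag_spec(config.lag_df, config.max_lag)
    cb = build_crossbasis(series.tmean, pred_spec, lag_spec, config.max_lag)
    if slope_temps is None:
        slope_temps = tuple(np.percentile(series.tmean, [50, 99]))
    grid = default_grid(series.tmean, config.grid_step)
    # snap the reference to the nearest grid point so RR(ref) is exactly 1
    ref = float(grid[np.argmin(np.abs(grid - np.median(series.tmean)))])

    out = {}
    for season, sub in split_by_season(series).items():
        fit = fit_season_model(series, sub, cb, config, category)
        out[season] = {
            "fit": fit,
            "curve": season_rr(fit, cb, grid, ref, config.ci_z),
            "slope": season_slope(fit, cb, *slope_temps, config.ci_z),
        }
    return out
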