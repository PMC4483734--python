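"""Model simplification: NCS-NCS -> DTHR-NCS -> STHR-NCS transitions.

The fully flexible natural-spline DLNM (NCS-NCS) is simplified in stages:

1. Fit NCS-NCS and compute the cumulative exposure-response curve.
2. Place double thresholds (DTHR) at the curve's local minima — the cold and
   heat arms become linear beyond the thresholds with a null region between —
   or a single high threshold (STHR) at the MMT when the curve has one
   minimum.
3. Grid-search candidate thresholds around stage 2 and select by a criterion
   (QAIC with a shared reference dispersion, or deviance explained).  When
   the low-threshold arm contributes nothing — its slope CI covers zero and an
   STHR fit is within 2 QAIC units of the optimum — the search collapses to a
   single high threshold.

All stages use the same lag basis and max lag, hence identical usable rows,
so fit criteria are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import BasisSpec, default_knots
from .config import AnalysisConfig
from .crossbasis import build_crossbasis, make_lag_spec
from .data_io import MortalityTimeSeries, derive_calendar_covariates
from .effects import ExposureResponseCurve, default_grid, find_mmt, predict_curve
from .glm import FitResult, assemble_design, deviance_explained, fit_quasipoisson, qaic

__all__ = [
    "ThresholdSpec",
    "TransitionReport",
    "locate_minima",
    "fit_threshold_model",
    "threshold_grid_search",
    "run_transition",
    "cumulative_threshold_slopes",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """Low and/or high temperature thresholds and how they were chosen."""

    low: float | None = None
    high: float | None = None
    source: str = "user"  # minima_of_ncs | grid_search | user

    def __post_init__(self):
        if self.low is None and self.high is None:
            raise ValueError("at least one threshold is required")
        if self.low is not None and self.high is not None and not self.low < self.high:
            raise ValueError(f"require low < high, got {self.low} >= {self.high}")

    @property
    def kind(self) -> str:
        return "dthr" if (self.low is not None and self.high is not None) else "sthr"

    def to_basis_spec(self) -> BasisSpec:
        if self.kind == "dthr":
            return BasisSpec(kind="dthr", thresholds=(self.low, self.high))
        return BasisSpec(kind="sthr", thresholds=(self.high,))


@dataclass
class TransitionReport:
    """Record of the three-stage transition: curves, criteria, search trace."""

    stages: dict = field(default_factory=dict)   # name -> stage record dict
    selected_stage: str | None = None
    equivalent: bool = False                     # all stages within 2 QAIC
    trace: pd.DataFrame | None = None
    row_hash: int | None = None

    def to_dict(self) -> dict:
        out = {"selected_stage": self.selected_stage, "equivalent": self.equivalent,
               "stages": {}}
        for name, st in self.stages.items():
            out["stages"][name] = {
                "thresholds": st.get("thresholds"),
                "qaic": st.get("qaic"),
                "deviance_explained": st.get("deviance_explained"),
                "dispersion": st.get("dispersion"),
                "mmt": st.get("mmt"),
            }
        return out

    def curves_frame(self) -> pd.DataFrame:
        """Long-format 3-panel curve table (the model-transition figure twin)."""
        parts = []
        for name, st in self.stages.items():
            f = st["curve"].to_frame()
            f.insert(0, "stage", name)
            parts.append(f)
        return pd.concat(parts, ignore_index=True)


def locate_minima(curve: ExposureResponseCurve, t_lo=None, t_hi=None) -> list[float]:
    """Interior local minima of the curve, ascending; plateaus collapse to
    their lowest-temperature point; empty for monotone curves."""
    g, y = curve.grid, curve.log_rr
    if t_lo is not None or t_hi is not None:
        mask = np.ones(len(g), bool)
        if t_lo is not None:
            mask &= g >= t_lo
        if t_hi is not None:
            mask &= g <= t_hi
        g, y = g[mask], y[mask]
    if len(g) < 3:
        return []
    # compress runs of equal values, remembering the first grid point of each run
    keep = np.concatenate([[True], np.diff(y) != 0])
    gc, yc = g[keep], y[keep]
    out = []
    for i in range(1, len(yc) - 1):
        if yc[i] < yc[i - 1] and yc[i] < yc[i + 1]:
            out.append(float(gc[i]))
    return out


def _threshold_design(series, thresholds: ThresholdSpec, lag_spec, max_lag, config):
    cb = build_crossbasis(series.tmean, thresholds.to_basis_spec(), lag_spec, max_lag)
    cov = derive_calendar_covariates(series, config.holidays)
    return cb, assemble_design(series, cb, cov, config)


def fit_threshold_model(
    series: MortalityTimeSeries,
    thresholds: ThresholdSpec,
    lag_spec: BasisSpec | None = None,
    max_lag: int | None = None,
    config: AnalysisConfig | None = None,
    category: str = "all",
):
    """Refit the model with a threshold predictor basis (STHR/DTHR) while
    keeping the NCS lag basis; returns ``(fit, curve, cb)`` with the curve
    centered in the null region (RR = 1 at and between the thresholds)."""
    config = config or AnalysisConfig()
    if max_lag is None:
        max_lag = config.max_lag
    if lag_spec is None:
        lag_spec = make_lag_spec(config.lag_df, max_lag)
    t_lo, t_hi = series.tmean.min(), series.tmean.max()
    for t in (thresholds.low, thresholds.high):
        if t is not None and not (t_lo <= t <= t_hi):
            raise ValueError(f"threshold {t} outside data range [{t_lo}, {t_hi}]")
    cb, (X, names, slices, rows) = _threshold_design(series, thresholds, lag_spec, max_lag, config)
    y = series.deaths[category].to_numpy()[rows]
    fit = fit_quasipoisson(y, X, names, slices)
    grid = default_grid(series.tmean, config.grid_step)
    ref = thresholds.high if thresholds.high is not None else thresholds.low
    curve = predict_curve(fit, cb, grid, ref=float(ref), ci_z=config.ci_z)
    curve.mmt = float(ref)
    return fit, curve, cb


def cumulative_threshold_slopes(fit: FitResult, cb) -> dict:
    """Cumulative per-°C slopes (and SEs) of a fitted threshold model.

    For a threshold basis each predictor column is piecewise linear with unit
    slope beyond its threshold, so the cumulative slope of arm j is
    ``sum_k beta_(j,k) * sum_l c_k(l)``.
    """
    from .crossbasis import lag_basis_matrix

    C = lag_basis_matrix(cb.lag_spec, cb.max_lag)
    csum = C.sum(axis=0)
    beta = fit.block_params("crossbasis")
    V = fit.block_cov("crossbasis")
    vx, vl = cb.vx, len(csum)
    out = {}
    arm_names = ["heat"] if vx == 1 else ["cold", "heat"]
    for j, arm in enumerate(arm_names):
        w = np.zeros(vx * vl)
        w[j * vl:(j + 1) * vl] = csum
        out[arm] = {
            "slope": float(w @ beta),
            "se": float(np.sqrt(max(w @ V @ w, 0.0))),
        }
    return out


def threshold_grid_search(
    series: MortalityTimeSeries,
    candidate_lows=None,
    candidate_highs=(),
    criterion: str = "qaic",
    config: AnalysisConfig | None = None,
    category: str = "all",
    phi_reference: float | None = None,
):
    """Evaluate STHR/DTHR fits over candidate thresholds and pick the best.

    Every candidate high is fitted as an STHR model; every (low, high) pair
    with low < high as a DTHR model.  Candidates are ranked by QAIC (shared
    reference dispersion) or deviance explained.  Among candidates within 2
    QAIC units of the optimum, an STHR model is preferred — the collapse to a
    single high threshold when the cold arm adds nothing — and otherwise the
    DTHR whose cold-arm slope is closest to null (smallest |z|) is kept.

    Returns ``(spec, trace)`` where ``trace`` is one row per candidate.
    """
    config = config or AnalysisConfig()
    candidate_highs = np.atleast_1d(np.asarray(candidate_highs, float))
    if candidate_highs.size == 0:
        raise ValueError("empty candidate grid")
    lows = (np.atleast_1d(np.asarray(candidate_lows, float))
            if candidate_lows is not None else np.array([]))
    lag_spec = make_lag_spec(config.lag_df, config.max_lag)

    records = []
    for high in candidate_highs:
        specs = [ThresholdSpec(high=float(high), source="grid_search")]
        for low in lows:
            if low < high:
                specs.append(ThresholdSpec(low=float(low), high=float(high),
                                           source="grid_search"))
        for spec in specs:
            fit, _, cb = fit_threshold_model(series, spec, lag_spec,
                                             config.max_lag, config, category)
            slopes = cumulative_threshold_slopes(fit, cb)
            cold = slopes.get("cold")
            records.append({
                "low": spec.low, "high": spec.high, "kind": spec.kind,
                "qaic": None, "loglik": fit.loglik, "rank": fit.rank,
                "dispersion": fit.dispersion,
                "deviance_explained": deviance_explained(fit),
                "cold_slope": cold["slope"] if cold else 0.0,
                "cold_z": (cold["slope"] / cold["se"]) if cold and cold["se"] > 0 else 0.0,
                "heat_slope": slopes["heat"]["slope"],
                "heat_se": slopes["heat"]["se"],
                "_fit": fit,
            })
    trace = pd.DataFrame(records)
    if phi_reference is None:
        # reference dispersion from the richest (highest-rank, then best loglik) fit
        order = trace.sort_values(["rank", "loglik"], ascending=[False, False])
        phi_reference = float(order.iloc[0]["dispersion"])
    trace["qaic"] = [qaic(f, phi_reference) for f in trace["_fit"]]

    if criterion == "qaic":
        best_val = trace["qaic"].min()
        near = trace[trace["qaic"] <= best_val + 2.0]
    elif criterion == "deviance_explained":
        best_val = trace["deviance_explained"].max()
        near = trace[trace["qaic"] <= trace.loc[trace["deviance_explained"].idxmax(), "qaic"] + 2.0]
    else:
        raise ValueError(f"unknown criterion '{criterion}'")

    sthr_near = near[near["kind"] == "sthr"]
    if len(sthr_near):
        pick = sthr_near.sort_values("qaic" if criterion == "qaic" else "deviance_explained",
                                     ascending=criterion == "qaic").iloc[0]
    else:
        # keep the DTHR whose cold arm is closest to null among near-optimal fits
        pick = near.assign(absz=near["cold_z"].abs()).sort_values(["absz", "qaic"]).iloc[0]
    spec = ThresholdSpec(
        low=None if pd.isna(pick["low"]) else float(pick["low"]),
        high=float(pick["high"]),
        source="grid_search",
    )
    return spec, trace.drop(columns="_fit")


def run_transition(
    series: MortalityTimeSeries,
    config: AnalysisConfig | None = None,
    category: str = "all",
) -> TransitionReport:
    """Execute the full three-stage simplification and report all stages."""
    config = config or AnalysisConfig()
    report = TransitionReport()
    lag_spec = make_lag_spec(config.lag_df, config.max_lag)
    pred_spec = default_knots(series.tmean, config.pred_df)

    # --- stage 1: NCS-NCS
    cb = build_crossbasis(series.tmean, pred_spec, lag_spec, config.max_lag)
    cov = derive_calendar_covariates(series, config.holidays)
    X, names, slices, rows = assemble_design(series, cb, cov, config)
    report.row_hash = hash(rows.tobytes())
    y = series.deaths[category].to_numpy()[rows]
    fit1 = fit_quasipoisson(y, X, names, slices)
    grid = default_grid(series.tmean, config.grid_step)
    w_lo, w_hi = np.percentile(series.tmean, config.mmt_window)
    prov = predict_curve(fit1, cb, grid, ref=float(np.median(series.tmean)), ci_z=config.ci_z)
    mmt = find_mmt(prov, w_lo, w_hi)
    curve1 = predict_curve(fit1, cb, grid, ref=mmt, ci_z=config.ci_z)
    curve1.mmt = mmt
    phi_ref = fit1.dispersion
    report.stages["ncs_ncs"] = {
        "fit": fit1, "curve": curve1, "thresholds": None, "mmt": mmt,
        "qaic": qaic(fit1, phi_ref), "deviance_explained": deviance_explained(fit1),
        "dispersion": fit1.dispersion,
    }

    # --- stage 2: thresholds at the NCS curve's minima
    b_lo, b_hi = np.percentile(series.tmean, config.threshold_percentile_bounds)
    minima = locate_minima(curve1, b_lo, b_hi)
    if len(minima) >= 2:
        spec2 = ThresholdSpec(low=minima[0], high=minima[-1], source="minima_of_ncs")
    else:
        spec2 = ThresholdSpec(high=minima[0] if minima else mmt, source="minima_of_ncs")
    fit2, curve2, cb2 = fit_threshold_model(series, spec2, lag_spec,
                                            config.max_lag, config, category)
    stage2_name = "dthr_ncs" if spec2.kind == "dthr" else "sthr_ncs_minima"
    report.stages[stage2_name] = {
        "fit": fit2, "curve": curve2, "thresholds": [spec2.low, spec2.high],
        "mmt": curve2.mmt, "qaic": qaic(fit2, phi_ref),
        "deviance_explained": deviance_explained(fit2), "dispersion": fit2.dispersion,
    }

    # --- stage 3: grid search around stage-2 thresholds
    step, w = config.grid_step, config.threshold_window
    highs = np.arange(spec2.high - w, spec2.high + w + step / 2, step)
    highs = highs[(highs >= b_lo) & (highs <= b_hi)]
    if spec2.low is not None:
        lows = np.arange(spec2.low - w, spec2.low + w + step / 2, step)
        lows = lows[(lows >= b_lo) & (lows <= b_hi)]
    else:
        lows = None
    spec3, trace = threshold_grid_search(series, lows, highs, config.criterion,
                                         config, category, phi_reference=phi_ref)
    fit3, curve3, cb3 = fit_threshold_model(series, spec3, lag_spec,
                                            config.max_lag, config, category)
    report.stages["sthr_ncs" if spec3.kind == "sthr" else "dthr_ncs_search"] = {
        "fit": fit3, "curve": curve3, "thresholds": [spec3.low, spec3.high],
        "mmt": curve3.mmt, "qaic": qaic(fit3, phi_ref),
        "deviance_explained": deviance_explained(fit3), "dispersion": fit3.dispersion,
    }
    report.trace = trace

    qaics = {name: st["qaic"] for name, st in report.stages.items()}
    report.selected_stage = min(qaics, key=qaics.get)
    report.equivalent = (max(qaics.values()) - min(qaics.values())) <= 2.0
    return report
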