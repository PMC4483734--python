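"""Analysis configuration shared by the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class AnalysisConfig:
    """Everything that affects estimates, in one serializable record.

    Defaults follow standard DLNM practice for a tropical daily series:
    NCS(df=4) in temperature × NCS(df=4, incl. lag intercept) over lags
    0..13, a long-term trend spline with 7 df per year, NCS(rh, 3), six
    day-of-week dummies and a holiday indicator.
    """

    pred_df: int = 4                 # temperature NCS df (NCS-NCS stage)
    lag_df: int = 4                  # lag basis columns incl. intercept
    max_lag: int = 13                # days
    trend_df_per_year: float = 7.0   # long-term trend spline, df per year
    rh_df: int = 3
    percentiles: tuple = (1, 5, 95, 99)
    mmt_window: tuple = (10, 90)     # percentile window for the MMT search
    grid_step: float = 0.1           # °C, exposure-response grid
    ci_z: float = 1.96               # 95% Wald multiplier on the log scale
    threshold_window: float = 1.5    # °C around stage-2 thresholds in the grid search
    threshold_percentile_bounds: tuple = (1, 99)
    criterion: str = "qaic"          # qaic | deviance_explained
    season_pred: str = "ncs"         # ncs | sthr | linear (season model predictor basis)
    season_sthr_threshold: float | None = None  # °C; default 75th percentile
    season_log_offset: float = 1.0   # log(deaths + offset) in the season model
    holidays: tuple = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["percentiles"] = list(self.percentiles)
        d["mmt_window"] = list(self.mmt_window)
        d["threshold_percentile_bounds"] = list(self.threshold_percentile_bounds)
        d["holidays"] = [str(h) for h in self.holidays]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f: d[f] for f in cls.__dataclass_fields__ if f in d}
        for f in ("percentiles", "mmt_window", "threshold_percentile_bounds", "holidays"):
            if f in known:
                known[f] = tuple(known[f])
        return cls(**known)
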