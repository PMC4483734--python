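"""Synthetic daily series with a known exposure-lag-response surface.

The generator emulates a multi-year tropical daily record — narrow
temperature range, seasonal humidity, day-of-week structure, overdispersed
counts — with ground truth attached, so every pipeline stage can be checked
against what it should recover.

Weather: temperature is a seasonal sinusoid plus AR(1) noise,

    T_t = mean + A sin(2 pi (doy_t - phase) / 365.25) + e_t,
    e_t = rho e_{t-1} + innovation,

calibrated to a Manila-like climate (mean 28.8 °C, overall SD ~1.5 °C,
warmest days in the MAM quarter).  Humidity is generated the same way with
the wet-season peak phase and clipped into (0, 100].

Mortality: the log mean is

    log mu_t = log(baseline) + s_t * m_cat + log dow_mult(t) + nuisance_t,

where s_t = sum_l f(T_{t-l}, l) is the true cumulative lag effect of the
configured surface, m_cat a per-category slope multiplier, and nuisance_t a
seasonal sinusoid confounder that the trend spline must absorb.  Counts are
Poisson, or gamma-mixed Poisson with variance omega * mu for overdispersion
omega > 1 (so the quasi-Poisson dispersion estimand is ~omega).  Category
counts are a temperature-dependent multinomial split of the daily total and
sum to it exactly.

Truth surfaces f(T, l) = g(T) * w_l with normalized lag weights w:

    null    g = 0
    sthr    g = heat_slope * max(0, T - high)
    dthr    g += cold_slope * max(0, low - T)
    ushape  piecewise quadratic, C1 at the MMT: g = a_h (T - mmt)^2 above,
            a_c (T - mmt)^2 below, with a_h = heat_slope / (2 (t_heat_ref -
            mmt)) and a_c = cold_slope / (2 (mmt - t_cold_ref)), i.e. the
            derivative at the reference hot/cold temperatures equals the
            stated slopes.

Randomness uses one seed with named substreams (weather / counts / split),
so changing one component's draws never shifts another's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_io import MortalityTimeSeries

__all__ = [
    "TempConfig",
    "RhConfig",
    "MortalityConfig",
    "TruthSurface",
    "CategoryConfig",
    "SyntheticConfig",
    "true_surface_logrr",
    "true_cumulative_logrr",
    "generate_weather",
    "generate_mortality",
    "generate_dataset",
]


@dataclass
class TempConfig:
    mean: float = 28.8            # °C
    amplitude: float = 1.1        # °C, seasonal sinusoid (MAM peak)
    phase_day: float = 44.0       # sinusoid peaks ~doy 135 (May)
    ar1: float = 0.7
    innovation_sd: float = 0.93   # °C; stationary SD ~1.3, total SD ~1.5


@dataclass
class RhConfig:
    mean: float = 73.9            # %
    amplitude: float = 4.0        # %, wet-season sinusoid (Aug peak)
    phase_day: float = 134.0
    ar1: float = 0.6
    innovation_sd: float = 5.0


@dataclass
class MortalityConfig:
    baseline: float = 52.0        # deaths/day, all-cause
    dow_multipliers: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 0.97, 0.97)
    overdispersion: float = 1.2   # omega; variance = omega * mean
    seasonal_amplitude: float = 0.03  # log-scale nuisance sinusoid
    seasonal_phase_day: float = 200.0


@dataclass
class TruthSurface:
    """Known exposure-lag-response surface f(T, l) = g(T) * w_l."""

    kind: str = "null"            # null | sthr | dthr | ushape
    mmt: float | None = None
    threshold_low: float | None = None
    threshold_high: float | None = None
    heat_slope: float = 0.0       # log-RR per °C
    cold_slope: float = 0.0       # log-RR per °C (positive = risk when colder)
    lag_weights: tuple = (0.4, 0.3, 0.2, 0.1)
    t_cold_ref: float = 25.5      # °C, ~1st percentile (ushape scaling)
    t_heat_ref: float = 32.0      # °C, ~99th percentile (ushape scaling)

    def __post_init__(self):
        w = np.asarray(self.lag_weights, float)
        if self.kind != "null" and (np.any(w < 0) or w.sum() <= 0):
            raise ValueError("lag weights must be non-negative with positive sum")
        if w.sum() > 0 and abs(w.sum() - 1.0) > 1e-12:  # idempotent normalization
            self.lag_weights = tuple(w / w.sum())
        else:
            self.lag_weights = tuple(w)
        if self.kind == "null":
            self.heat_slope = 0.0
            self.cold_slope = 0.0


@dataclass
class CategoryConfig:
    name: str
    share: float
    slope_multiplier: float = 1.0


@dataclass
class SyntheticConfig:
    n_years: int = 5
    start: str = "2006-01-01"
    temp: TempConfig = field(default_factory=TempConfig)
    rh: RhConfig = field(default_factory=RhConfig)
    mortality: MortalityConfig = field(default_factory=MortalityConfig)
    surface: TruthSurface = field(default_factory=TruthSurface)
    categories: tuple = ()        # CategoryConfig records; shares must sum to 1
    season_multipliers: dict | None = None  # season -> surface multiplier

    def __post_init__(self):
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.categories:
            total = sum(c.share for c in self.categories)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"category shares sum to {total}, expected 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["categories"] = [asdict(c) for c in self.categories]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        return cls(
            n_years=d.get("n_years", 5),
            start=d.get("start", "2006-01-01"),
            temp=TempConfig(**d.get("temp", {})),
            rh=RhConfig(**d.get("rh", {})),
            mortality=MortalityConfig(**{
                **d.get("mortality", {}),
                "dow_multipliers": tuple(d.get("mortality", {}).get(
                    "dow_multipliers", MortalityConfig().dow_multipliers)),
            }),
            surface=TruthSurface(**{
                **d.get("surface", {}),
                "lag_weights": tuple(d.get("surface", {}).get(
                    "lag_weights", TruthSurface().lag_weights)),
            }),
            categories=tuple(CategoryConfig(**c) for c in d.get("categories", [])),
            season_multipliers=d.get("season_multipliers"),
        )


def _surface_g(surface: TruthSurface, temp) -> np.ndarray:
    """Temperature part g(T) of the truth surface (cumulative log-RR scale)."""
    t = np.asarray(temp, float)
    if surface.kind == "null":
        return np.zeros_like(t)
    if surface.kind == "sthr":
        return surface.heat_slope * np.maximum(0.0, t - surface.threshold_high)
    if surface.kind == "dthr":
        return (surface.heat_slope * np.maximum(0.0, t - surface.threshold_high)
                + surface.cold_slope * np.maximum(0.0, surface.threshold_low - t))
    if surface.kind == "ushape":
        mmt = surface.mmt
        a_h = surface.heat_slope / (2.0 * (surface.t_heat_ref - mmt))
        a_c = surface.cold_slope / (2.0 * (mmt - surface.t_cold_ref))
        d = t - mmt
        return np.where(d >= 0, a_h * d**2, a_c * d**2)
    raise ValueError(f"unknown surface kind '{surface.kind}'")


def true_surface_logrr(surface: TruthSurface, temp, lag: int) -> np.ndarray:
    """f(T, l): log-RR contribution of temperature ``temp`` at lag ``lag``."""
    w = surface.lag_weights
    if not 0 <= lag < len(w):
        raise ValueError(f"lag {lag} outside profile support 0..{len(w) - 1}")
    return _surface_g(surface, temp) * w[lag]


def true_cumulative_logrr(surface: TruthSurface, temp) -> np.ndarray:
    """Cumulative (over lags) true log-RR at ``temp``; equals g(T) since the
    lag weights are normalized."""
    return _surface_g(surface, temp)


def _doy(dates: pd.DatetimeIndex) -> np.ndarray:
    return dates.dayofyear.to_numpy(float)


def _seasonal(dates, amplitude, phase_day) -> np.ndarray:
    return amplitude * np.sin(2 * np.pi * (_doy(dates) - phase_day) / 365.25)


def _ar1(n, rho, innovation_sd, rng) -> np.ndarray:
    if not 0 <= rho < 1:
        raise ValueError("ar1 coefficient must be in [0, 1)")
    e = np.empty(n)
    stat_sd = innovation_sd / np.sqrt(1 - rho**2) if innovation_sd > 0 else 0.0
    e[0] = rng.normal(0, stat_sd) if stat_sd > 0 else 0.0
    shocks = rng.normal(0, innovation_sd, n - 1) if innovation_sd > 0 else np.zeros(n - 1)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + shocks[i - 1]
    return e


def generate_weather(config: SyntheticConfig, seed_or_rng):
    """Daily dates, temperature and humidity series for ``n_years`` years."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    n = int(round(config.n_years * 365.25))
    dates = pd.date_range(config.start, periods=n, freq="D")
    tc, rc = config.temp, config.rh
    tmean = tc.mean + _seasonal(dates, tc.amplitude, tc.phase_day) \
        + _ar1(n, tc.ar1, tc.innovation_sd, rng)
    rh = rc.mean + _seasonal(dates, rc.amplitude, rc.phase_day) \
        + _ar1(n, rc.ar1, rc.innovation_sd, rng)
    rh = np.clip(rh, 30.0, 100.0)
    return dates, tmean, rh


def _season_multiplier(config: SyntheticConfig, dates) -> np.ndarray:
    if not config.season_multipliers:
        return np.ones(len(dates))
    from .data_io import _SEASON_OF_MONTH

    return np.array([
        config.season_multipliers.get(_SEASON_OF_MONTH[m], 1.0) for m in dates.month
    ])


def true_daily_effect(config: SyntheticConfig, dates, tmean) -> np.ndarray:
    """s_t: cumulative true log-RR applied to day t (lags truncated at the
    series start; the first max-lag rows are dropped downstream anyway)."""
    w = np.asarray(config.surface.lag_weights, float)
    g = _surface_g(config.surface, tmean)
    n = len(tmean)
    s = np.zeros(n)
    for lag, wl in enumerate(w):
        if wl == 0:
            continue
        s[lag:] += wl * g[: n - lag]
    return s * _season_multiplier(config, dates)


def generate_mortality(config: SyntheticConfig, dates, tmean, rng_counts, rng_split):
    """Daily death counts (total + category split) with ground truth."""
    mc = config.mortality
    if len(mc.dow_multipliers) != 7:
        raise ValueError("need 7 day-of-week multipliers")
    s = true_daily_effect(config, dates, tmean)
    dow_mult = np.asarray(mc.dow_multipliers, float)[dates.dayofweek]
    nuisance = _seasonal(dates, mc.seasonal_amplitude, mc.seasonal_phase_day)
    log_mu = np.log(mc.baseline) + s + np.log(dow_mult) + nuisance
    if np.any(log_mu > 20):
        raise ValueError("mean overflow; use smaller slopes or baseline")
    mu = np.exp(log_mu)

    omega = mc.overdispersion
    if omega < 1:
        raise ValueError("overdispersion must be >= 1")
    if omega == 1:
        total = rng_counts.poisson(mu)
    else:
        k = mu / (omega - 1.0)  # gamma-Poisson: variance = omega * mu
        total = rng_counts.negative_binomial(k, k / (k + mu))

    deaths = {"all": total}
    if config.categories:
        shares = np.array([c.share for c in config.categories])
        mults = np.array([c.slope_multiplier for c in config.categories])
        # temperature-dependent split: p_i(t) proportional to share_i * exp((m_i - 1) s_t)
        logits = np.log(shares)[None, :] + (mults - 1.0)[None, :] * s[:, None]
        p = np.exp(logits - logits.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        split = np.empty((len(total), len(shares)), dtype=int)
        for i in range(len(total)):
            split[i] = rng_split.multinomial(total[i], p[i])
        for j, c in enumerate(config.categories):
            deaths[c.name] = split[:, j]
    truth = {
        "surface": asdict(config.surface),
        "cumulative_logrr": s,
        "log_mu": log_mu,
    }
    return pd.DataFrame(deaths), truth


def generate_dataset(config: SyntheticConfig | None = None, seed: int = 0):
    """Full synthetic dataset: validated series plus the truth bundle.

    One seed, three named substreams (weather / counts / split); two calls
    with the same config and seed are identical.
    """
    config = config or SyntheticConfig()
    ss = np.random.SeedSequence(seed)
    rng_weather, rng_counts, rng_split = (np.random.default_rng(s) for s in ss.spawn(3))
    dates, tmean, rh = generate_weather(config, rng_weather)
    deaths, truth = generate_mortality(config, dates, tmean, rng_counts, rng_split)
    series = MortalityTimeSeries(dates=dates, tmean=tmean, rh=rh, deaths=deaths).validate()
    truth["config"] = config.to_dict()
    truth["seed"] = seed
    return series, truth


def truth_to_json(truth: dict) -> str:
    out = {k: v for k, v in truth.items() if k not in ("cumulative_logrr", "log_mu")}
    return json.dumps(out, indent=2, default=float)
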