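"""Reading, validation and summarisation of daily mortality time series.

The central container is :class:`MortalityTimeSeries`: a strictly contiguous
daily record of mean temperature (°C), mean relative humidity (%) and one or
more non-negative integer death-count columns (all-cause plus cause-, sex-,
age-specific categories).  Lagged-exposure modelling requires contiguity, so
date gaps are a hard error by default; ``allow_gaps=True`` splits the input
into contiguous segments instead of imputing.

Seasons follow the PAGASA climatological quarters used for the Philippines:
DJF (northeast monsoon), MAM (summer), JJA (southwest monsoon), SON
(transition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "MortalityTimeSeries",
    "CalendarCovariates",
    "read_timeseries",
    "write_timeseries",
    "read_holidays",
    "classify_season",
    "derive_calendar_covariates",
    "summary_statistics",
    "SEASONS",
]

SEASONS = ("DJF", "MAM", "JJA", "SON")

_SEASON_OF_MONTH = {
    12: "DJF", 1: "DJF", 2: "DJF",
    3: "MAM", 4: "MAM", 5: "MAM",
    6: "JJA", 7: "JJA", 8: "JJA",
    9: "SON", 10: "SON", 11: "SON",
}


class SchemaError(ValueError):
    """Input file does not have the required columns."""


class ValidationError(ValueError):
    """Input data violate a series invariant (gaps, negative counts, ...)."""


@dataclass
class MortalityTimeSeries:
    """Contiguous daily series of exposure, humidity and death counts.

    Parameters
    ----------
    dates
        Strictly increasing daily ``DatetimeIndex`` with step exactly 1 day.
    tmean
        Daily mean temperature, °C.
    rh
        Daily mean relative humidity, % in (0, 100].
    deaths
        One integer column per mortality category (e.g. ``all``, ``cvd``,
        ``resp``, ``male``, ``female``, age bands).
    """

    dates: pd.DatetimeIndex
    tmean: np.ndarray
    rh: np.ndarray
    deaths: pd.DataFrame

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.tmean = np.asarray(self.tmean, dtype=float)
        self.rh = np.asarray(self.rh, dtype=float)
        self.deaths = pd.DataFrame(self.deaths).reset_index(drop=True)

    @property
    def categories(self) -> list[str]:
        return list(self.deaths.columns)

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def n_years(self) -> float:
        return len(self) / 365.25

    def validate(self) -> "MortalityTimeSeries":
        """Check all container invariants; raise ``ValidationError`` on failure."""
        n = len(self.dates)
        if n == 0:
            raise ValidationError("empty series")
        if self.dates.has_duplicates:
            dup = self.dates[self.dates.duplicated()][0]
            raise ValidationError(f"duplicate date {dup.date()}")
        steps = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        if np.any(steps <= 0):
            raise ValidationError("dates are not strictly increasing")
        if np.any(steps != 1):
            i = int(np.argmax(steps != 1))
            raise ValidationError(
                f"date gap between {self.dates[i].date()} and "
                f"{self.dates[i + 1].date()} ({steps[i] - 1} missing day(s))"
            )
        for arr, name in ((self.tmean, "tmean"), (self.rh, "rh")):
            if len(arr) != n:
                raise ValidationError(f"{name} length {len(arr)} != {n} dates")
            if not np.all(np.isfinite(arr)):
                row = int(np.argmin(np.isfinite(arr)))
                raise ValidationError(f"non-finite {name} at row {row}")
        if np.any(self.rh <= 0) or np.any(self.rh > 100):
            row = int(np.argmax((self.rh <= 0) | (self.rh > 100)))
            raise ValidationError(f"rh out of (0, 100] at row {row}")
        if len(self.deaths) != n:
            raise ValidationError("death counts length does not match dates")
        if not self.categories:
            raise ValidationError("no death-count categories")
        for cat in self.categories:
            col = self.deaths[cat].to_numpy()
            as_float = np.asarray(col, dtype=float)
            if not np.all(np.isfinite(as_float)):
                row = int(np.argmin(np.isfinite(as_float)))
                raise ValidationError(f"non-finite count in '{cat}' at row {row}")
            if np.any(as_float != np.round(as_float)):
                row = int(np.argmax(as_float != np.round(as_float)))
                raise ValidationError(f"non-integer count in '{cat}' at row {row}")
            if np.any(as_float < 0):
                row = int(np.argmax(as_float < 0))
                raise ValidationError(f"negative count in '{cat}' at row {row}")
            self.deaths[cat] = as_float.astype(int)
        return self

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "date": self.dates.strftime("%Y-%m-%d"),
            "tmean": self.tmean,
            "rh": self.rh,
        })
        for cat in self.categories:
            out[cat] = self.deaths[cat].to_numpy()
        return out

    @property
    def season(self) -> np.ndarray:
        """PAGASA season label per day."""
        return np.array([_SEASON_OF_MONTH[m] for m in self.dates.month])


@dataclass
class CalendarCovariates:
    """Deterministic calendar covariates aligned with a series.

    ``dow`` uses the Monday=0 convention; ``time_index`` counts days from the
    series start; ``hod`` flags supplied holidays.
    """

    dow: np.ndarray
    hod: np.ndarray
    doy: np.ndarray
    time_index: np.ndarray
    season: np.ndarray
    holidays: tuple = field(default_factory=tuple)


def classify_season(date) -> str:
    """PAGASA season of a date: DJF / MAM / JJA / SON, by month alone."""
    return _SEASON_OF_MONTH[pd.Timestamp(date).month]


def read_timeseries(path, category_columns=None, allow_gaps: bool = False):
    """Read and validate a daily CSV (``date,tmean,rh,<categories...>``).

    Returns a validated :class:`MortalityTimeSeries`, or a list of contiguous
    segments when ``allow_gaps=True`` and the file contains date gaps.
    """
    frame = pd.read_csv(path)
    for col in ("date", "tmean", "rh"):
        if col not in frame.columns:
            raise SchemaError(f"missing required column '{col}'")
    if category_columns is None:
        category_columns = [c for c in frame.columns if c not in ("date", "tmean", "rh")]
    for col in category_columns:
        if col not in frame.columns:
            raise SchemaError(f"missing category column '{col}'")
    if not category_columns:
        raise SchemaError("no death-count category columns in file")
    frame["date"] = pd.to_datetime(frame["date"], format="%Y-%m-%d")

    def _build(sub: pd.DataFrame) -> MortalityTimeSeries:
        return MortalityTimeSeries(
            dates=pd.DatetimeIndex(sub["date"]),
            tmean=sub["tmean"].to_numpy(float),
            rh=sub["rh"].to_numpy(float),
            deaths=sub[category_columns],
        ).validate()

    if allow_gaps:
        gaps = frame["date"].diff().dt.days.fillna(1).to_numpy() != 1
        segment = np.cumsum(gaps)
        return [_build(sub) for _, sub in frame.groupby(segment)]
    return _build(frame)


def write_timeseries(series: MortalityTimeSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_holidays(path) -> list[pd.Timestamp]:
    """Read a one-ISO-date-per-line holiday file (blank lines ignored)."""
    with open(path) as fh:
        return [pd.Timestamp(line.strip()) for line in fh if line.strip()]


def derive_calendar_covariates(series: MortalityTimeSeries, holidays=()) -> CalendarCovariates:
    """Day-of-week, holiday flag, day-of-year, time index and season labels."""
    holidays = tuple(pd.Timestamp(h) for h in holidays)
    outside = [h for h in holidays if h < series.dates[0] or h > series.dates[-1]]
    if outside:
        warnings.warn(
            f"{len(outside)} holiday(s) outside series range ignored", stacklevel=2
        )
    hol = pd.DatetimeIndex(holidays)
    return CalendarCovariates(
        dow=series.dates.dayofweek.to_numpy(),
        hod=series.dates.isin(hol).astype(int),
        doy=series.dates.dayofyear.to_numpy(),
        time_index=np.arange(len(series)),
        season=series.season,
        holidays=holidays,
    )


_STATS = ("mean", "sd", "min", "p10", "p50", "p90", "max")


def _row(values: np.ndarray) -> dict:
    values = np.asarray(values, float)
    p10, p50, p90 = np.percentile(values, [10, 50, 90])  # type-7 linear interpolation
    return {
        "mean": values.mean(),
        "sd": values.std(ddof=1) if len(values) > 1 else 0.0,
        "min": values.min(),
        "p10": p10,
        "p50": p50,
        "p90": p90,
        "max": values.max(),
    }


def summary_statistics(series: MortalityTimeSeries, by_season: bool = False) -> pd.DataFrame:
    """Descriptive summary per variable (and per PAGASA season if requested).

    Percentiles use linear interpolation between order statistics (type 7),
    the convention fixed for all percentile temperatures in the package.
    """
    if len(series) == 0:
        raise ValidationError("empty series")
    variables = [("tmean", series.tmean), ("rh", series.rh)] + [
        (cat, series.deaths[cat].to_numpy()) for cat in series.categories
    ]
    rows = {}
    for name, values in variables:
        rows[(name, "all")] = _row(values)
        if by_season:
            labels = series.season
            for s in SEASONS:
                mask = labels == s
                if mask.any():
                    rows[(name, s)] = _row(values[mask])
    table = pd.DataFrame.from_dict(rows, orient="index", columns=_STATS)
    table.index = pd.MultiIndex.from_tuples(table.index, names=["variable", "season"])
    return table
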