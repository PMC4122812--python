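"""Temperature features: daily means, 5-day running means, local minima.

The onset models are driven by two features of the pre-season weather: the
5-day trailing running mean of a daily temperature statistic (maximum for
Alnus/Corylus, mean for Betula), and "local minima" of that running-mean
series — short dips (at least two strictly decreasing steps followed by at
least two strictly increasing steps) that empirically precede the start of
early tree pollen seasons.

Daily mean temperature follows the four-observation climatological
convention (t_max + t_min + t_06 + t_18) / 4, with the fixed-hour readings
taken at 06:00 and 18:00 UTC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np
import pandas as pd

from .errors import GapError, ValidationError

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 5  # days in the trailing running-mean window

WEATHER_COLUMNS = ["date", "t_min", "t_max", "t_06", "t_18"]
TEMP_FIELDS = ["t_min", "t_max", "t_06", "t_18"]


@dataclass(frozen=True)
class MeteoDay:
    """One day's raw temperature observations (°C)."""

    date: Date
    t_min: float
    t_max: float
    t_06: float
    t_18: float

    def __post_init__(self):
        for name in TEMP_FIELDS:
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValidationError(
                    f"{self.date}: field {name!r} is missing or non-finite"
                )
        if self.t_min > self.t_max:
            raise ValidationError(f"{self.date}: t_min > t_max")


@dataclass(frozen=True)
class LocalMinimum:
    """A detected dip in a running-mean temperature series."""

    day: int  # day of year, 1-based (Jan 1 = 1)
    r_value: float  # running-mean value at that day, °C


@dataclass
class RunningMeanSeries:
    """Trailing 5-day running means of a daily statistic, indexed by day of year."""

    year: int
    statistic: str  # "max" or "mean"
    values: pd.Series  # index: day of year (int), values: °C
    window_length: int = WINDOW_LENGTH
    dates: pd.Series | None = field(default=None, repr=False)

    @property
    def first_day(self) -> int:
        return int(self.values.index[0])


def daily_mean_temperature(day) -> float:
    """Mean daily temperature, (t_max + t_min + t_06 + t_18) / 4.

    Accepts a :class:`MeteoDay`, a mapping, or a pandas row with the four
    temperature fields.
    """
    if isinstance(day, MeteoDay):
        vals = (day.t_max, day.t_min, day.t_06, day.t_18)
    else:
        try:
            vals = tuple(day[k] for k in ("t_max", "t_min", "t_06", "t_18"))
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"missing temperature field: {exc}") from exc
    arr = np.asarray(vals, dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = [k for k, v in zip(("t_max", "t_min", "t_06", "t_18"), arr)
               if not np.isfinite(v)]
        when = getattr(day, "date", None) or (day.get("date") if hasattr(day, "get") else "?")
        raise ValidationError(f"{when}: non-finite temperature field(s) {bad}")
    return float(arr.sum() / 4.0)


def read_weather_csv(path) -> pd.DataFrame:
    """Read a daily weather CSV (``date,t_min,t_max,t_06,t_18``, ISO dates, °C)."""
    df = pd.read_csv(path)
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"weather CSV missing column(s) {missing}")
    if len(df) == 0:
        raise ValidationError("weather CSV contains no rows")
    df["date"] = pd.to_datetime(df["date"])
    return validate_weather(df)


def validate_weather(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by date, enforce uniqueness and the per-day temperature invariants."""
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values("date").reset_index(drop=True)
    if df["date"].duplicated().any():
        dup = df.loc[df["date"].duplicated(), "date"].iloc[0].date()
        raise ValidationError(f"duplicate weather date {dup}")
    bad = df["t_min"] > df["t_max"]
    if bad.any():
        when = df.loc[bad, "date"].iloc[0].date()
        raise ValidationError(f"{when}: t_min > t_max")
    return df


def prepare_series(df: pd.DataFrame, max_gap: int = 2) -> pd.DataFrame:
    """Reindex to a contiguous daily series, interpolating short gaps.

    Gaps of at most ``max_gap`` consecutive missing days are filled by linear
    interpolation per temperature field (logged); longer gaps raise
    :class:`GapError` — years with long outages are excluded from analysis
    rather than patched.
    """
    df = validate_weather(df)
    full = pd.date_range(df["date"].iloc[0], df["date"].iloc[-1], freq="D")
    out = df.set_index("date").reindex(full)
    missing = out[TEMP_FIELDS[0]].isna()
    if missing.any():
        # length of each run of consecutive missing days
        runs = missing.astype(int).groupby((~missing).cumsum()).sum()
        longest = int(runs.max())
        if longest > max_gap:
            raise GapError(
                f"gap of {longest} consecutive days exceeds the "
                f"{max_gap}-day interpolation limit"
            )
        n = int(missing.sum())
        logger.warning("interpolating %d missing day(s) in weather series", n)
        out[TEMP_FIELDS] = out[TEMP_FIELDS].interpolate(method="linear")
    out.index.name = "date"
    return out.reset_index()


def running_means(
    series: pd.DataFrame,
    statistic: str,
    first_day,
    year: int | None = None,
    max_gap: int = 2,
) -> RunningMeanSeries:
    """Trailing 5-day running means of a daily temperature statistic.

    Parameters
    ----------
    series : DataFrame with ``date,t_min,t_max,t_06,t_18`` columns. Must cover
        the four days preceding ``first_day`` (for a Jan 1 start this means
        Dec 28–31 of the previous year).
    statistic : ``"max"`` (daily maximum) or ``"mean"`` (four-observation
        daily mean).
    first_day : first day carrying a running mean — an int day of year, a
        ``(month, day)`` tuple, or a date.
    year : the calendar year of interest; inferred from the data if omitted.

    The value at day *d* is the arithmetic mean of the statistic over the five
    consecutive calendar days *d−4 … d* (no look-ahead).
    """
    if statistic not in ("max", "mean"):
        raise ValidationError(f"unknown running-mean statistic {statistic!r}")
    df = prepare_series(series, max_gap=max_gap)
    if year is None:
        year = int(df["date"].dt.year.max())
    first_date = _resolve_day(first_day, year)

    daily = df["t_max"] if statistic == "max" else df[TEMP_FIELDS].sum(axis=1) / 4.0
    rm = daily.rolling(WINDOW_LENGTH).mean()

    dates = df["date"]
    needed = first_date - pd.Timedelta(days=WINDOW_LENGTH - 1)
    if dates.iloc[0] > needed:
        first_ok = dates.iloc[0] + pd.Timedelta(days=WINDOW_LENGTH - 1)
        raise ValidationError(
            f"insufficient leading history before {first_date.date()}: "
            f"first computable running-mean day is {first_ok.date()}"
        )
    mask = (dates >= first_date) & (dates.dt.year == year)
    if not mask.any():
        raise ValidationError(f"no data on or after {first_date.date()} in {year}")
    sel_dates = dates[mask]
    values = pd.Series(
        rm[mask].to_numpy(), index=sel_dates.dt.dayofyear.to_numpy(), name="running_mean"
    )
    return RunningMeanSeries(
        year=year, statistic=statistic, values=values,
        dates=pd.Series(sel_dates.dt.date.to_numpy(), index=values.index),
    )


def _resolve_day(first_day, year: int) -> pd.Timestamp:
    if isinstance(first_day, tuple):
        return pd.Timestamp(year, first_day[0], first_day[1])
    if isinstance(first_day, (int, np.integer)):
        return pd.Timestamp(year, 1, 1) + pd.Timedelta(days=int(first_day) - 1)
    return pd.Timestamp(first_day)


def detect_local_minima(
    rms: RunningMeanSeries | pd.Series,
    min_decrease_days: int = 2,
    min_increase_days: int = 2,
    last_day: int | None = None,
) -> list[LocalMinimum]:
    """Find "local minima": dips flanked by strict monotone runs.

    A day *d* qualifies when the series has at least ``min_decrease_days``
    strictly decreasing steps into *d* and at least ``min_increase_days``
    strictly increasing steps out of *d*. A tied step terminates a run, so
    plateaus never qualify. Days within a flank's reach of the series edges
    are ineligible (their flanks are unobservable). ``last_day`` truncates
    the series before searching, e.g. at an observed season start.
    """
    values = rms.values if isinstance(rms, RunningMeanSeries) else rms
    if len(values) == 0:
        return []
    days = np.asarray(values.index, dtype=int)
    if np.any(np.diff(days) != 1):
        raise ValidationError("running-mean day index is not contiguous")
    v = values.to_numpy(dtype=float)
    if last_day is not None:
        keep = days <= last_day
        days, v = days[keep], v[keep]
    n = len(v)
    out: list[LocalMinimum] = []
    for i in range(min_decrease_days, n - min_increase_days):
        if all(v[i - k - 1] > v[i - k] for k in range(min_decrease_days)) and all(
            v[i + k] < v[i + k + 1] for k in range(min_increase_days)
        ):
            out.append(LocalMinimum(day=int(days[i]), r_value=float(v[i])))
    return out


def running_means_frame(rms: RunningMeanSeries) -> pd.DataFrame:
    """Running means as a flat table (``year,day_of_year,date,statistic,running_mean``)."""
    return pd.DataFrame(
        {
            "year": rms.year,
            "day_of_year": rms.values.index,
            "date": rms.dates.to_numpy() if rms.dates is not None else pd.NaT,
            "statistic": rms.statistic,
            "running_mean": rms.values.to_numpy(),
        }
    )


def minima_frame(year: int, minima: list[LocalMinimum]) -> pd.DataFrame:
    """Local minima as a flat table (``year,day_of_year,running_mean``)."""
    return pd.DataFrame(
        {
            "year": year,
            "day_of_year": [m.day for m in minima],
            "running_mean": [m.r_value for m in minima],
        }
    )
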