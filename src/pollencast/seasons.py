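"""Pollen season starts by the cumulative-sum method, and their statistics.

The season start for a taxon is the first day on which the cumulative sum of
daily airborne pollen concentrations, accumulated from a fixed calendar date,
reaches a taxon-specific threshold (5 grains from Jan 1 for Alnus and
Corylus, 15 grains from Mar 1 for Betula). Starts are classified as early /
moderate / late (E/M/L) by fixed day-of-year ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NoSeasonError, ValidationError

TAXA = ("alnus", "corylus", "betula")


@dataclass(frozen=True)
class TaxonConfig:
    """Per-taxon season-definition parameters."""

    taxon: str
    cum_threshold: float  # grains; cumulative sum that marks the start
    accumulation_start: tuple[int, int]  # (month, day) accumulation begins
    rm_statistic: str  # running-mean statistic the onset model uses
    rm_start: tuple[int, int]  # (month, day) first running-mean day
    season_type_bounds: dict[str, tuple[int, int]]  # inclusive E/M/L ranges

    def __post_init__(self):
        if self.cum_threshold <= 0:
            raise ValidationError("cum_threshold must be positive")
        b = self.season_type_bounds
        if set(b) != {"E", "M", "L"}:
            raise ValidationError("season_type_bounds must define E, M and L")
        if not (b["E"][1] + 1 == b["M"][0] and b["M"][1] + 1 == b["L"][0]):
            raise ValidationError("E/M/L ranges must be contiguous and ordered")


DEFAULT_CONFIGS: dict[str, TaxonConfig] = {
    "alnus": TaxonConfig(
        taxon="alnus",
        cum_threshold=5.0,
        accumulation_start=(1, 1),
        rm_statistic="max",
        rm_start=(1, 1),
        season_type_bounds={"E": (12, 36), "M": (37, 60), "L": (61, 84)},
    ),
    "corylus": TaxonConfig(
        taxon="corylus",
        cum_threshold=5.0,
        accumulation_start=(1, 1),
        rm_statistic="max",
        rm_start=(1, 1),
        season_type_bounds={"E": (11, 36), "M": (37, 61), "L": (62, 85)},
    ),
    "betula": TaxonConfig(
        taxon="betula",
        cum_threshold=15.0,
        accumulation_start=(3, 1),
        rm_statistic="mean",
        rm_start=(3, 5),
        season_type_bounds={"E": (87, 95), "M": (96, 104), "L": (105, 113)},
    ),
}


def taxon_config(taxon: str) -> TaxonConfig:
    """Default configuration for one of the three studied taxa."""
    try:
        return DEFAULT_CONFIGS[taxon.lower()]
    except KeyError:
        raise ValidationError(f"unknown taxon {taxon!r}; expected one of {TAXA}")


def equal_period_bounds(min_day: int, max_day: int) -> dict[str, tuple[int, int]]:
    """Derive E/M/L bounds by splitting [min_day, max_day] into three equal periods.

    Auxiliary constructor for new sites/taxa; the bundled per-taxon defaults
    take precedence for Alnus, Corylus and Betula.
    """
    if max_day <= min_day:
        raise ValidationError("max_day must exceed min_day")
    edges = np.linspace(min_day, max_day + 1, 4)
    lo = [int(np.ceil(e)) for e in edges[:3]]
    hi = [l - 1 for l in lo[1:]] + [int(max_day)]
    return {"E": (lo[0], hi[0]), "M": (lo[1], hi[1]), "L": (lo[2], hi[2])}


@dataclass(frozen=True)
class SeasonStart:
    """Per-taxon, per-year season onset."""

    taxon: str
    year: int
    day: int  # day of year, 1-based
    date: Date
    season_type: str | None  # "E", "M", "L", or None if outside typing range


@dataclass(frozen=True)
class SeasonStats:
    """Descriptive statistics of a sample of season-start days."""

    n: int
    mean: float
    median: float
    sd: float  # sample SD (n-1 denominator)
    cv: float  # coefficient of variation, % (100*SD/mean)
    min: int
    max: int
    ci_lower: float  # 95% CI of the mean (t distribution, n-1 df)
    ci_upper: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n", "mean", "median", "sd", "cv", "min", "max", "ci_lower", "ci_upper")}


def classify_season_type(day: int, config: TaxonConfig) -> str:
    """Map a season-start day of year to its E/M/L type."""
    for label, (lo, hi) in config.season_type_bounds.items():
        if lo <= day <= hi:
            return label
    raise ValidationError(
        f"day {day} is outside the {config.taxon} E/M/L typing range "
        f"{config.season_type_bounds['E'][0]}–{config.season_type_bounds['L'][1]}"
    )


def season_start(pollen, config: TaxonConfig, year: int | None = None) -> SeasonStart:
    """First day whose cumulative pollen sum reaches the taxon threshold.

    ``pollen`` is a date-indexed Series of daily concentrations (grains/m³)
    or a DataFrame with ``date`` and ``concentration`` columns. Accumulation
    runs from the configured start date; the threshold is attained with
    ``>=`` on the cumulative sum.
    """
    s = _as_series(pollen)
    if (s < 0).any():
        raise ValidationError("negative pollen concentration")
    if year is None:
        year = int(s.index[-1].year)
    start_date = pd.Timestamp(year, *config.accumulation_start)
    s = s[s.index >= start_date].sort_index()
    if len(s) == 0:
        raise NoSeasonError(
            f"{config.taxon} {year}: no pollen data on or after {start_date.date()}",
            attained=0.0,
        )
    csum = s.cumsum()
    hit = csum[csum >= config.cum_threshold]
    if len(hit) == 0:
        raise NoSeasonError(
            f"{config.taxon} {year}: cumulative sum reached only "
            f"{csum.iloc[-1]:.2f} of threshold {config.cum_threshold}",
            attained=float(csum.iloc[-1]),
        )
    when = hit.index[0]
    day = int(when.dayofyear)
    try:
        stype = classify_season_type(day, config)
    except ValidationError:
        stype = None
    return SeasonStart(taxon=config.taxon, year=year, day=day,
                       date=when.date(), season_type=stype)


def season_stats(starts) -> SeasonStats:
    """Descriptive statistics (mean, median, SD, CV%, range, 95% CI) of start days."""
    days = np.asarray(
        [s.day if isinstance(s, SeasonStart) else s for s in starts], dtype=float
    )
    n = len(days)
    if n < 2:
        raise ValidationError("need at least 2 season starts (SD undefined)")
    mean = float(days.mean())
    sd = float(days.std(ddof=1))
    sem = sd / np.sqrt(n)
    half = float(stats.t.ppf(0.975, n - 1) * sem)
    return SeasonStats(
        n=n,
        mean=mean,
        median=float(np.median(days)),
        sd=sd,
        cv=float(100.0 * sd / mean),
        min=int(days.min()),
        max=int(days.max()),
        ci_lower=mean - half,
        ci_upper=mean + half,
    )


def read_pollen_csv(path) -> pd.DataFrame:
    """Read a pollen CSV (``date,taxon,concentration``)."""
    df = pd.read_csv(path)
    missing = [c for c in ("date", "taxon", "concentration") if c not in df.columns]
    if missing:
        raise ValidationError(f"pollen CSV missing column(s) {missing}")
    df["date"] = pd.to_datetime(df["date"])
    return df


def season_starts_frame(starts: list[SeasonStart]) -> pd.DataFrame:
    """Season starts as a flat table (``taxon,year,day_of_year,date,season_type``)."""
    return pd.DataFrame(
        {
            "taxon": [s.taxon for s in starts],
            "year": [s.year for s in starts],
            "day_of_year": [s.day for s in starts],
            "date": [s.date for s in starts],
            "season_type": [s.season_type for s in starts],
        }
    )


def _as_series(pollen) -> pd.Series:
    if isinstance(pollen, pd.DataFrame):
        if "concentration" not in pollen.columns or "date" not in pollen.columns:
            raise ValidationError("pollen frame needs 'date' and 'concentration'")
        s = pollen.set_index(pd.to_datetime(pollen["date"]))["concentration"]
    elif isinstance(pollen, pd.Series):
        s = pollen.copy()
        s.index = pd.to_datetime(s.index)
    else:
        raise ValidationError("pollen must be a Series or DataFrame")
    return s.astype(float)
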