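"""End-to-end orchestration: weather + pollen → features → fit → reports.

`run_pipeline` chains the stages for one taxon across all years present in
the pollen data: 5-day running means, local minima (capped at each year's
detected season start), cumulative-sum season starts, labelled training
cases, the logistic fit with diagnostics, the in-sample classification
table, and (optionally) verification of held-out years with the frozen
coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import PollencastError, ValidationError
from .meteo import LocalMinimum, detect_local_minima, running_means, validate_weather
from .model import Coefficients, OnsetLogit, fit_onset_model
from .seasons import SeasonStart, TaxonConfig, season_start, taxon_config
from .training import (
    ClassificationTable,
    TrainingCase,
    VerificationRow,
    build_training_cases,
    classification_table,
    verify,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline-level knobs; defaults are the study conventions."""

    window: int = 10  # forecast window (days after a minimum)
    exclusion: int = 3  # training exclusion margin (days before the start)
    threshold: float = 0.5  # decision threshold on the forecast probability
    min_decrease_days: int = 2  # strict down-steps required into a minimum
    min_increase_days: int = 2  # strict up-steps required out of a minimum
    interpolation_limit: int = 2  # max gap (days) filled by interpolation

    def __post_init__(self):
        if not (self.window > self.exclusion >= 0):
            raise ValidationError("need window > exclusion >= 0")
        if not 0.0 < self.threshold < 1.0:
            raise ValidationError("threshold must lie in (0, 1)")


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    taxon: str
    starts: list[SeasonStart]
    minima_by_year: dict[int, list[LocalMinimum]]
    cases: list[TrainingCase]
    model: OnsetLogit | None
    table: ClassificationTable | None
    verification: dict[int, list[VerificationRow]] = field(default_factory=dict)


def year_features(
    weather: pd.DataFrame,
    pollen: pd.DataFrame,
    config: TaxonConfig,
    run: RunConfig,
    year: int,
) -> tuple[SeasonStart, list[LocalMinimum]]:
    """Season start and pre-season local minima for one year."""
    start = season_start(_pollen_for_year(pollen, config, year), config, year=year)
    wslice = _weather_for_year(weather, year)
    rms = running_means(
        wslice, config.rm_statistic, config.rm_start, year=year,
        max_gap=run.interpolation_limit,
    )
    minima = detect_local_minima(
        rms,
        min_decrease_days=run.min_decrease_days,
        min_increase_days=run.min_increase_days,
        last_day=start.day,
    )
    return start, minima


def run_pipeline(
    weather: pd.DataFrame,
    pollen: pd.DataFrame,
    taxon: str | TaxonConfig,
    run: RunConfig | None = None,
    fit_years=None,
    verify_years=None,
) -> PipelineResult:
    """Run the full onset-modelling pipeline for one taxon.

    ``fit_years``/``verify_years`` split the study: the model is fitted on
    ``fit_years`` (default: all years not held out) and verification rows
    are produced for ``verify_years`` with the fitted coefficients frozen.
    """
    config = taxon if isinstance(taxon, TaxonConfig) else taxon_config(taxon)
    run = run or RunConfig()
    if len(weather) == 0:
        raise ValidationError("stage features: empty weather input")
    if len(pollen) == 0:
        raise ValidationError("stage onset: empty pollen input")
    weather = validate_weather(weather)
    pollen = pollen.copy()
    pollen["date"] = pd.to_datetime(pollen["date"])

    years = sorted(
        pollen.loc[pollen["taxon"].str.lower() == config.taxon, "date"].dt.year.unique()
    )
    if not years:
        raise ValidationError(f"stage onset: no pollen rows for taxon {config.taxon}")
    verify_years = sorted(verify_years or [])
    fit_years = sorted(fit_years) if fit_years is not None else [
        y for y in years if y not in verify_years
    ]
    overlap = set(fit_years) & set(verify_years)
    if overlap:
        raise ValidationError(f"fit and verify years overlap: {sorted(overlap)}")

    starts: list[SeasonStart] = []
    minima_by_year: dict[int, list[LocalMinimum]] = {}
    for year in years:
        try:
            start, minima = year_features(weather, pollen, config, run, year)
        except PollencastError as exc:
            raise type(exc)(f"{config.taxon} {year}: {exc}") from exc
        starts.append(start)
        minima_by_year[year] = minima
        logger.info("%s %d: start day %d, %d minima",
                    config.taxon, year, start.day, len(minima))

    cases = build_training_cases(
        {y: m for y, m in minima_by_year.items() if y in fit_years},
        [s for s in starts if s.year in fit_years],
        window=run.window,
        exclusion=run.exclusion,
        taxon=config.taxon,
    )
    model = table = None
    if cases:
        model = fit_onset_model(cases)
        table = classification_table(model, cases, threshold=run.threshold)

    verification: dict[int, list[VerificationRow]] = {}
    if verify_years:
        if model is None:
            raise ValidationError("verification requested but no model was fitted")
        coeffs = model.to_coefficients()
        start_by_year = {s.year: s for s in starts}
        for year in verify_years:
            verification[year] = verify(
                coeffs, minima_by_year[year], start_by_year[year],
                window=run.window, threshold=run.threshold, year=year,
            )
    return PipelineResult(
        taxon=config.taxon,
        starts=starts,
        minima_by_year=minima_by_year,
        cases=cases,
        model=model,
        table=table,
        verification=verification,
    )


def holdout_verify(
    weather: pd.DataFrame,
    pollen: pd.DataFrame,
    taxon: str | TaxonConfig,
    fit_years,
    verify_years,
    run: RunConfig | None = None,
) -> PipelineResult:
    """Fit on ``fit_years`` only; verify frozen coefficients on ``verify_years``."""
    fit_years, verify_years = set(fit_years), set(verify_years)
    if fit_years & verify_years:
        raise ValidationError("fit and verify year sets must be disjoint")
    return run_pipeline(
        weather, pollen, taxon, run=run,
        fit_years=sorted(fit_years), verify_years=sorted(verify_years),
    )


def _weather_for_year(weather: pd.DataFrame, year: int) -> pd.DataFrame:
    lo = pd.Timestamp(year - 1, 12, 15)
    hi = pd.Timestamp(year, 5, 15)
    mask = (weather["date"] >= lo) & (weather["date"] <= hi)
    out = weather.loc[mask]
    if len(out) == 0:
        raise ValidationError("no weather rows in the pre-season window")
    return out


def _pollen_for_year(pollen: pd.DataFrame, config: TaxonConfig, year: int):
    mask = (pollen["taxon"].str.lower() == config.taxon) & (
        pollen["date"].dt.year == year
    )
    out = pollen.loc[mask]
    if len(out) == 0:
        raise ValidationError("no pollen rows for this year")
    return out[["date", "concentration"]]
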