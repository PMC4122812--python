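"""Synthetic weather and pollen studies for end-to-end testing.

Real multi-decade pollen/weather series for the three taxa are not publicly
deposited, so the pipeline ships a generator producing datasets with the
statistical structure the analysis assumes: winter/spring daily temperatures
as a seasonal sinusoid (coldest mid-January) plus AR(1) Gaussian noise —
rough enough to show several pre-season running-mean dips per year — and
pollen-count series engineered so the cumulative sum first reaches the taxon
threshold exactly on a prescribed start day.

Season onset is generated through the onset model's own hazard: walking the
year's local minima in day order, each triggers the season with probability
logistic(β0 + βd·day + βt·t5); on the first success the start day is drawn
uniformly 3–10 days later (outside the training exclusion margin, inside the
forecast window). This makes parameter recovery by the downstream logistic
fit a well-posed check of the whole pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .meteo import LocalMinimum, detect_local_minima, running_means
from .model import Coefficients, predict_probability, reference_coefficients
from .seasons import TaxonConfig, taxon_config

MIN_OFFSET = 3  # smallest start offset after the triggering minimum
MAX_OFFSET = 10  # largest; equals the forecast window


@dataclass
class SimulationScenario:
    """Parameters of a synthetic multi-year study.

    Defaults emulate a Central-European winter/spring: January mean daily
    temperature near −2 °C rising to ~19 °C in July (amplitude 10.5 °C),
    day-to-day anomalies with standard deviation 3 °C and lag-1
    autocorrelation 0.7 — enough synoptic-scale roughness that the 5-day
    running mean shows roughly two to six local minima per late winter, as
    observed series do. Diurnal offsets place t_max ≈ mean+4 °C,
    t_min ≈ mean−4 °C and the 06:00/18:00 readings in between.
    """

    n_years: int = 20
    seed: int = 0
    start_year: int = 1991
    winter_mean: float = -2.0  # °C, mid-January mean daily temperature
    annual_amplitude: float = 10.5  # °C, half peak-to-peak of the seasonal cycle
    ar1: float = 0.7  # lag-1 autocorrelation of daily anomalies
    noise_sd: float = 3.0  # °C, stationary SD of daily anomalies
    diurnal_offsets: dict = field(
        default_factory=lambda: {"t_max": 4.0, "t_min": -4.0, "t_06": -2.0, "t_18": 1.5}
    )
    offset_noise_sd: float = 0.5  # °C, independent jitter on each observation
    taxon: str = "alnus"
    true_coefficients: Coefficients | None = None  # default: bundled reference set
    pollen_peak: float = 80.0  # grains/m³ at the season's crest
    pollen_spread: float = 8.0  # days, Gaussian width of the season curve
    pollen_noise: float = 0.4  # lognormal sigma of daily count noise

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not 0 <= self.ar1 < 1:
            raise ValidationError("AR(1) coefficient must lie in [0, 1)")
        if self.annual_amplitude < 0:
            raise ValidationError("annual amplitude must be non-negative")
        if self.true_coefficients is None:
            self.true_coefficients = reference_coefficients(self.taxon)

    @classmethod
    def from_yaml(cls, path) -> "SimulationScenario":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "true_coefficients" in payload and payload["true_coefficients"] is not None:
            payload["true_coefficients"] = Coefficients(**payload["true_coefficients"])
        return cls(**payload)


@dataclass
class StudyBundle:
    """A complete synthetic study plus its generating truth."""

    weather: pd.DataFrame  # date,t_min,t_max,t_06,t_18 — all years
    pollen: pd.DataFrame  # date,taxon,concentration — all years
    truth: dict  # true coefficients, per-year starts/minima/trigger
    config: TaxonConfig


def simulate_temperature(
    scenario: SimulationScenario, year_index: int, stream: int = 0
) -> pd.DataFrame:
    """One winter/spring of daily observations, Dec 20 (prior year) – Apr 30.

    Daily mean = seasonal sinusoid with its minimum in mid-January plus an
    AR(1) anomaly; the four per-day observations are the mean plus diurnal
    offsets and small independent jitter, re-ordered so t_min ≤ t_06, t_18 ≤
    t_max always holds. Deterministic given (seed, year_index, stream).
    """
    year = scenario.start_year + year_index
    rng = np.random.default_rng([scenario.seed, year_index, stream, 0])
    dates = pd.date_range(f"{year - 1}-12-20", f"{year}-04-30", freq="D")
    # signed day offset from Jan 15 of the target year (sinusoid minimum)
    t = (dates - pd.Timestamp(year, 1, 15)).days.to_numpy(float)
    seasonal = scenario.winter_mean + scenario.annual_amplitude * (
        1.0 - np.cos(2.0 * np.pi * t / 365.25)
    )
    innov_sd = scenario.noise_sd * np.sqrt(1.0 - scenario.ar1**2)
    anom = np.empty(len(dates))
    anom[0] = rng.normal(0.0, scenario.noise_sd)
    shocks = rng.normal(0.0, innov_sd, size=len(dates) - 1)
    for i in range(1, len(dates)):
        anom[i] = scenario.ar1 * anom[i - 1] + shocks[i - 1]
    mean = seasonal + anom

    obs = {}
    for name in ("t_min", "t_max", "t_06", "t_18"):
        obs[name] = (
            mean
            + scenario.diurnal_offsets[name]
            + rng.normal(0.0, scenario.offset_noise_sd, size=len(dates))
        )
    stacked = np.vstack([obs[k] for k in ("t_min", "t_max", "t_06", "t_18")])
    t_min = stacked.min(axis=0)
    t_max = stacked.max(axis=0)
    return pd.DataFrame(
        {
            "date": dates,
            "t_min": t_min,
            "t_max": t_max,
            "t_06": np.clip(obs["t_06"], t_min, t_max),
            "t_18": np.clip(obs["t_18"], t_min, t_max),
        }
    )


def simulate_onset(
    minima: list[LocalMinimum],
    true_c: Coefficients,
    rng: np.random.Generator,
) -> int | None:
    """Draw a season start from the model hazard over the year's local minima.

    Walks the minima in ascending day order; each triggers with probability
    logistic(β0 + βd·day + βt·t5). The first success at day *d* yields a
    start drawn uniformly from {d+3, …, d+10}; returns ``None`` when no
    minimum triggers ("no onset" — callers typically resimulate the year).
    """
    start, _ = _draw_onset(minima, true_c, rng)
    return start


def _draw_onset(minima, true_c, rng):
    if not minima:
        raise ValidationError("no local minima to draw an onset from")
    days = [m.day for m in minima]
    if days != sorted(days):
        raise ValidationError("minima must be in ascending day order")
    for m in minima:
        p = float(predict_probability(true_c, m.day, m.r_value))
        if rng.random() < p:
            return int(m.day + rng.integers(MIN_OFFSET, MAX_OFFSET + 1)), int(m.day)
    return None, None


def simulate_pollen(
    start_day: int,
    scenario: SimulationScenario,
    rng: np.random.Generator,
    year: int,
    config: TaxonConfig | None = None,
) -> pd.DataFrame:
    """Daily pollen counts whose cumulative sum first hits the threshold on ``start_day``.

    Pre-start days carry trace counts summing to strictly less than the
    threshold (an exponential ramp toward the start); the start day tops the
    cumulative sum up past the threshold; afterwards a noisy bell-shaped
    season curve follows. The cumulative-sum season-start rule therefore
    recovers ``start_day`` exactly.
    """
    config = config or taxon_config(scenario.taxon)
    acc = pd.Timestamp(year, *config.accumulation_start)
    acc_doy = int(acc.dayofyear)
    if start_day < acc_doy:
        raise ValidationError("start_day precedes the accumulation start")
    end_doy = start_day + 45
    days = np.arange(acc_doy, end_doy + 1)
    conc = np.zeros(len(days), dtype=float)

    pre = days < start_day
    n_pre = int(pre.sum())
    if n_pre > 0:
        budget = rng.uniform(0.2, 0.75) * config.cum_threshold
        w = np.exp((days[pre] - start_day) / 5.0)
        conc[pre] = budget * w / w.sum()
    pre_total = conc[pre].sum()

    post = days >= start_day
    bell = scenario.pollen_peak * np.exp(
        -(((days[post] - (start_day + 12)) / scenario.pollen_spread) ** 2)
    )
    noise = rng.lognormal(0.0, scenario.pollen_noise, size=int(post.sum()))
    conc[post] = np.maximum(bell * noise, 0.0)
    # guarantee the threshold is first reached exactly on the start day
    deficit = config.cum_threshold - pre_total
    if conc[post][0] < deficit:
        conc[np.argmax(post)] = deficit + rng.uniform(0.0, 1.0)

    dates = acc + pd.to_timedelta(days - acc_doy, unit="D")
    return pd.DataFrame(
        {"date": dates, "taxon": config.taxon, "concentration": conc}
    )


def make_study(
    scenario: SimulationScenario,
    outdir=None,
    max_attempts: int = 25,
    last_search_day: int = 110,
) -> StudyBundle:
    """Generate a complete n-year study (weather + pollen + truth).

    Per year: simulate temperatures, extract the taxon's running-mean series,
    detect local minima up to ``last_search_day``, draw the onset through the
    model hazard, and synthesize a pollen series hitting the cumulative
    threshold on that day. Years in which no minimum triggers (or the onset
    falls too late in spring) are resimulated on a fresh, deterministic
    substream. Writing ``weather.csv``, ``pollen.csv`` and ``truth.json`` to
    ``outdir`` is optional; rerunning with the same scenario is byte-identical.
    """
    config = taxon_config(scenario.taxon)
    weather_parts, pollen_parts = [], []
    truth_years = []
    for yi in range(scenario.n_years):
        year = scenario.start_year + yi
        for attempt in range(max_attempts):
            wdf = simulate_temperature(scenario, yi, stream=attempt)
            rms = running_means(wdf, config.rm_statistic, config.rm_start, year=year)
            minima = detect_local_minima(rms, last_day=last_search_day)
            if not minima:
                continue
            rng_onset = np.random.default_rng([scenario.seed, yi, attempt, 1])
            start, trigger = _draw_onset(minima, scenario.true_coefficients, rng_onset)
            if start is not None and start <= last_search_day + MAX_OFFSET:
                break
        else:
            raise ValidationError(
                f"year {year}: no onset triggered in {max_attempts} attempts"
            )
        rng_pollen = np.random.default_rng([scenario.seed, yi, attempt, 2])
        pdf = simulate_pollen(start, scenario, rng_pollen, year, config)
        weather_parts.append(wdf)
        pollen_parts.append(pdf)
        truth_years.append(
            {
                "year": year,
                "start_day": int(start),
                "trigger_day": int(trigger),
                "attempt": attempt,
                "minima": [[int(m.day), float(m.r_value)] for m in minima],
            }
        )
    weather = pd.concat(weather_parts, ignore_index=True)
    pollen = pd.concat(pollen_parts, ignore_index=True)
    truth = {
        "taxon": scenario.taxon,
        "seed": scenario.seed,
        "true_coefficients": asdict(scenario.true_coefficients),
        "offset_rule": f"uniform {{{MIN_OFFSET}..{MAX_OFFSET}}} days after the triggering minimum; non-triggering years resimulated",
        "years": truth_years,
    }
    bundle = StudyBundle(weather=weather, pollen=pollen, truth=truth, config=config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        w = weather.copy()
        w["date"] = w["date"].dt.date
        w.to_csv(outdir / "weather.csv", index=False, float_format="%.3f")
        p = pollen.copy()
        p["date"] = p["date"].dt.date
        p.to_csv(outdir / "pollen.csv", index=False, float_format="%.3f")
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return bundle
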