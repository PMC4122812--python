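"""Labelled training cases, forecast verification and classification tables.

Each detected pre-season local minimum becomes one binary case: label 1 when
the pollen season started within the 10-day window after the minimum, else 0.
Minima falling less than three days before the start are excluded from
training (their outcome is trivially foreseeable); verification of held-out
years applies no such exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IncompleteYearError, ValidationError
from .meteo import LocalMinimum
from .model import Coefficients, OnsetLogit, predict_probability
from .seasons import SeasonStart

DEFAULT_WINDOW = 10  # days after a minimum within which the season may start
DEFAULT_EXCLUSION = 3  # minima closer than this to the start are not trained on


@dataclass(frozen=True)
class TrainingCase:
    """One labelled local minimum."""

    taxon: str
    year: int
    day: int
    t5: float
    label: int  # 1 iff season started within the window after the minimum


@dataclass(frozen=True)
class VerificationRow:
    """One verification line: model forecast vs observed outcome."""

    year: int
    day: int
    t5: float
    probability: float  # reported probability (rounded to `decimals`)
    forecast: bool  # YES iff probability > threshold
    observed: bool  # did the season start within the window?


@dataclass(frozen=True)
class ClassificationTable:
    """In-sample confusion counts at the 0.5 decision threshold."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def pct_correct_yes(self) -> float:
        """% correct among observed season starts."""
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def pct_correct_no(self) -> float:
        """% correct among observed non-starts."""
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def pct_correct_overall(self) -> float:
        total = self.tp + self.fn + self.fp + self.tn
        return 100.0 * (self.tp + self.tn) / total

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "pct_correct_yes": self.pct_correct_yes,
            "pct_correct_no": self.pct_correct_no,
            "pct_correct_overall": self.pct_correct_overall,
        }


def label_for_offset(offset: int, window: int = DEFAULT_WINDOW) -> int:
    """1 iff the season started 1..window days after the minimum."""
    return int(1 <= offset <= window)


def build_training_cases(
    minima_by_year: dict[int, list[LocalMinimum]],
    starts,
    window: int = DEFAULT_WINDOW,
    exclusion: int = DEFAULT_EXCLUSION,
    taxon: str | None = None,
) -> list[TrainingCase]:
    """Turn per-year minima plus observed season starts into labelled cases.

    For a minimum at day *d* and a start at day *s*: the case is dropped when
    ``s − d < exclusion`` (too close to train on, or not before the start at
    all); otherwise the label is 1 iff ``1 ≤ s − d ≤ window``. Cases are
    ordered by year then day.
    """
    if window <= exclusion:
        raise ValidationError("window must exceed the exclusion margin")
    start_by_year = _start_map(starts)
    cases: list[TrainingCase] = []
    for year in sorted(minima_by_year):
        minima = minima_by_year[year]
        if not minima:
            continue
        if year not in start_by_year:
            raise IncompleteYearError(
                f"year {year} has local minima but no observed season start"
            )
        s_obj = start_by_year[year]
        s = s_obj.day if isinstance(s_obj, SeasonStart) else int(s_obj)
        tx = taxon or (s_obj.taxon if isinstance(s_obj, SeasonStart) else "?")
        for m in sorted(minima, key=lambda m: m.day):
            offset = s - m.day
            if offset < exclusion:
                continue
            cases.append(TrainingCase(
                taxon=tx, year=year, day=m.day, t5=m.r_value,
                label=label_for_offset(offset, window),
            ))
    return cases


def cases_to_xy(cases):
    """Training cases → (X, y) arrays with columns [day, t5]."""
    if isinstance(cases, pd.DataFrame):
        return cases[["day", "t5"]].to_numpy(float), cases["label"].to_numpy(float)
    X = np.array([[c.day, c.t5] for c in cases], dtype=float)
    y = np.array([c.label for c in cases], dtype=float)
    return X, y


def cases_frame(cases: list[TrainingCase]) -> pd.DataFrame:
    """Cases as a flat table (``taxon,year,day,t5,label``)."""
    return pd.DataFrame(
        {
            "taxon": [c.taxon for c in cases],
            "year": [c.year for c in cases],
            "day": [c.day for c in cases],
            "t5": [c.t5 for c in cases],
            "label": [c.label for c in cases],
        }
    )


def verify(
    coefficients: Coefficients,
    minima: list[LocalMinimum],
    start,
    window: int = DEFAULT_WINDOW,
    threshold: float = 0.5,
    year: int | None = None,
    decimals: int | None = 2,
) -> list[VerificationRow]:
    """Score fixed coefficients against one held-out year.

    One row per local minimum: the model probability, the YES/NO forecast,
    and whether the season actually began within the window. No proximity
    exclusion applies — minima arbitrarily close to the start are scored.

    Probabilities are reported rounded to ``decimals`` places and the > 0.5
    rule is applied to the reported value, keeping the report self-consistent
    with its own probability column (coefficients are typically published to
    three decimals, so finer digits of the probability are not meaningful).
    Pass ``decimals=None`` to threshold the exact probability.
    """
    s = start.day if isinstance(start, SeasonStart) else int(start)
    if year is None and isinstance(start, SeasonStart):
        year = start.year
    rows: list[VerificationRow] = []
    for m in sorted(minima, key=lambda m: m.day):
        p = float(predict_probability(coefficients, m.day, m.r_value))
        p_rep = round(p, decimals) if decimals is not None else p
        rows.append(VerificationRow(
            year=year if year is not None else -1,
            day=m.day,
            t5=m.r_value,
            probability=p_rep,
            forecast=p_rep > threshold,
            observed=bool(label_for_offset(s - m.day, window)),
        ))
    return rows


def verification_frame(rows: list[VerificationRow]) -> pd.DataFrame:
    """Verification rows as a flat table mirroring a forecast-report layout."""
    return pd.DataFrame(
        {
            "year": [r.year for r in rows],
            "day": [r.day for r in rows],
            "t5": [r.t5 for r in rows],
            "probability": [r.probability for r in rows],
            "forecast": ["YES" if r.forecast else "NO" for r in rows],
            "observed": ["YES" if r.observed else "NO" for r in rows],
        }
    )


def classification_table(
    fit: OnsetLogit | Coefficients,
    cases,
    threshold: float = 0.5,
) -> ClassificationTable:
    """Confusion counts of the fitted model on its own training cases.

    In-sample accounting (no cross-validation): probabilities are computed on
    the training cases themselves and thresholded strictly at ``threshold``.
    """
    X, y = cases_to_xy(cases)
    if len(y) == 0:
        raise ValidationError("no cases to classify")
    if isinstance(fit, Coefficients):
        p = predict_probability(fit, X[:, 0], X[:, 1])
    else:
        p = fit.predict_proba(X)[:, 1]
    pred = p > threshold
    obs = y == 1
    return ClassificationTable(
        tp=int(np.sum(pred & obs)),
        fn=int(np.sum(~pred & obs)),
        fp=int(np.sum(pred & ~obs)),
        tn=int(np.sum(~pred & ~obs)),
    )


def _start_map(starts) -> dict[int, object]:
    if isinstance(starts, dict):
        return starts
    out = {}
    for s in starts:
        out[s.year] = s
    return out
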