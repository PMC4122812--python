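"""Shared fixtures: reference model inputs and a synthetic study bundle."""

import numpy as np
import pandas as pd
import pytest

import pollencast as pc

# Season-start day-of-year samples for the 1991-2010 reference period
# (Alnus/Corylus exclude 1992 and 1996, lost to instrument outages).
ALNUS_START_DAYS = [67, 36, 12, 39, 55, 43, 35, 40, 39, 25, 66, 51, 77, 84, 14, 20, 63, 66]
CORYLUS_START_DAYS = [67, 36, 13, 38, 55, 45, 36, 41, 39, 31, 70, 48, 76, 85, 11, 21, 63, 74]
BETULA_START_DAYS = [96, 105, 111, 91, 109, 113, 90, 93, 94, 104, 97, 87, 103, 97, 99, 101, 98, 97, 97, 90]

# Held-out verification inputs (2011-2012): per (taxon, year) the local-minimum
# days, the running-mean temperature on each, the observed season-start day,
# the reference-model probabilities at 2 d.p., and the expected YES/NO cells.
VERIFICATION_TABLE = {
    ("alnus", 2011): dict(
        days=[6, 25, 33], t5=[0.9, -0.1, -0.7], start=42,
        probs=[0.05, 0.12, 0.18],
        forecast=[False, False, False], observed=[False, False, True],
    ),
    ("alnus", 2012): dict(
        days=[10, 18, 36, 43, 60], t5=[4.3, 0.0, -12.4, -8.6, 5.6], start=66,
        probs=[0.11, 0.08, 0.03, 0.09, 0.80],
        forecast=[False, False, False, False, True],
        observed=[False, False, False, False, True],
    ),
    ("corylus", 2011): dict(
        days=[6, 25, 33], t5=[0.9, -0.1, -0.7], start=43,
        probs=[0.03, 0.09, 0.13],
        forecast=[False, False, False], observed=[False, False, True],
    ),
    # day 60: start 73 is 13 days later (outside the 10-day window) and the
    # model probability 0.82 exceeds 0.5, so the rule-consistent cells are
    # forecast YES / observed NO.
    ("corylus", 2012): dict(
        days=[10, 18, 36, 43, 60, 68], t5=[4.3, 0.0, -12.4, -8.6, 5.6, 3.7], start=73,
        probs=[0.08, 0.06, 0.02, 0.06, 0.82, 0.84],
        forecast=[False, False, False, False, True, True],
        observed=[False, False, False, False, False, True],
    ),
    ("betula", 2011): dict(
        days=[80, 89], t5=[3.4, 5.56], start=96,
        probs=[0.09, 0.72],
        forecast=[False, True], observed=[False, True],
    ),
    ("betula", 2012): dict(
        days=[67, 82, 86, 93], t5=[-1.84, 8.38, 8.68, 5.52], start=94,
        probs=[0.00, 0.50, 0.77, 0.88],
        forecast=[False, False, True, True], observed=[False, False, True, True],
    ),
}


@pytest.fixture(scope="session")
def coeffs():
    return {t: pc.reference_coefficients(t) for t in ("alnus", "corylus", "betula")}


@pytest.fixture(scope="session")
def study20():
    """A deterministic 20-year synthetic Alnus study."""
    scenario = pc.SimulationScenario(n_years=20, seed=3)
    return scenario, pc.make_study(scenario)


@pytest.fixture()
def weather_frame():
    """A smooth 60-day weather frame starting Dec 28 (valid Jan 1 history)."""
    dates = pd.date_range("1999-12-28", periods=60, freq="D")
    base = np.linspace(0.0, 6.0, 60)
    return pd.DataFrame({
        "date": dates,
        "t_min": base - 3.0,
        "t_max": base + 3.0,
        "t_06": base - 1.0,
        "t_18": base + 1.0,
    })


def rm_series(values, first_day=1, year=2000, statistic="max"):
    """Wrap raw values as a RunningMeanSeries for detector tests."""
    idx = np.arange(first_day, first_day + len(values))
    return pc.RunningMeanSeries(
        year=year, statistic=statistic,
        values=pd.Series(np.asarray(values, float), index=idx),
    )


def brute_force_minima(values, first_day=1, down=2, up=2):
    """Exhaustive day-by-day flank scan (independent oracle)."""
    v = np.asarray(values, float)
    out = []
    for i in range(len(v)):
        if i < down or i >= len(v) - up:
            continue
        ok = all(v[i - k - 1] > v[i - k] for k in range(down)) and all(
            v[i + k] < v[i + k + 1] for k in range(up)
        )
        if ok:
            out.append((first_day + i, v[i]))
    return out
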