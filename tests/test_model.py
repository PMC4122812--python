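"""The logistic onset model: prediction, fitting, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from sklearn.base import clone
from sklearn.model_selection import cross_val_score

import pollencast as pc
from pollencast.errors import SeparationError, ValidationError


def simulate_cases(c, n, rng):
    X = np.column_stack([rng.uniform(5, 80, n), rng.normal(0, 5, n)])
    p = expit(c.beta0 + c.beta_day * X[:, 0] + c.beta_t * X[:, 1])
    return X, (rng.random(n) < p).astype(int)


class TestPredict:
    def test_formula_oracle_on_random_inputs(self, coeffs):
        rng = np.random.default_rng(9)
        c = coeffs["alnus"]
        for _ in range(1000):
            d, t = rng.uniform(1, 120), rng.uniform(-15, 15)
            expect = 1.0 / (1.0 + np.exp(-(c.beta0 + c.beta_day * d + c.beta_t * t)))
            assert pc.predict(c, d, t).probability == pytest.approx(expect, abs=1e-12)

    def test_zero_coefficients_give_half(self):
        f = pc.predict(pc.Coefficients(0, 0, 0), 57, -3.2)
        assert f.probability == 0.5
        assert f.decision is False  # strict > 0.5

    def test_stable_at_extreme_linear_predictor(self):
        c = pc.Coefficients(-700, 0, 0)
        assert pc.predict(c, 1, 1).probability == pytest.approx(0.0)
        c = pc.Coefficients(700, 0, 0)
        assert pc.predict(c, 1, 1).probability == pytest.approx(1.0)

    def test_logistic_symmetry_under_negated_predictor(self, coeffs):
        c = coeffs["corylus"]
        neg = pc.Coefficients(-c.beta0, -c.beta_day, -c.beta_t)
        for d, t in [(30, -5.0), (60, 2.5), (80, 8.0)]:
            assert pc.predict(c, d, t).probability + pc.predict(neg, d, t).probability \
                == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_input_rejected(self, coeffs):
        with pytest.raises(ValidationError):
            pc.predict(coeffs["alnus"], np.nan, 0.0)


class TestOddsAndCrossing:
    def test_delta_zero_is_identity(self, coeffs):
        assert pc.odds_multiplier(coeffs["betula"], "day", 0.0) == 1.0

    def test_crossing_day_roundtrip(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            c = pc.Coefficients(rng.normal(0, 3), rng.uniform(0.01, 0.5),
                                rng.normal(0, 0.4))
            t5 = rng.uniform(-10, 10)
            p = rng.uniform(0.05, 0.95)
            d = pc.day_at_probability(c, t5, p)
            assert pc.predict_probability(c, d, t5) == pytest.approx(p, abs=1e-10)

    def test_crossing_at_zero_day(self):
        c = pc.Coefficients(-1.0, 0.1, 0.5)
        t5 = 2.0  # beta0 + beta_t*t5 = 0
        assert pc.day_at_probability(c, t5, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_zero_day_slope_rejected(self):
        with pytest.raises(ValidationError):
            pc.day_at_probability(pc.Coefficients(-1, 0, 0.5), 0.0)


class TestProbabilityCurve:
    def test_strictly_increasing_when_day_slope_positive(self, coeffs):
        curve = pc.probability_curve(coeffs["alnus"], -4.0, np.arange(1, 121))
        assert (np.diff(curve["probability"]) > 0).all()

    def test_warmer_curve_dominates_pointwise(self, coeffs):
        days = np.arange(1, 121)
        cold = pc.probability_curve(coeffs["alnus"], -4.0, days)["probability"]
        warm = pc.probability_curve(coeffs["alnus"], 6.0, days)["probability"]
        assert (warm.to_numpy() > cold.to_numpy()).all()

    def test_curve_equals_elementwise_predict(self, coeffs):
        c = coeffs["betula"]
        curve = pc.probability_curve(c, 2.0, np.arange(60, 120))
        for d, p in zip(curve["day"], curve["probability"]):
            assert p == pytest.approx(pc.predict(c, d, 2.0).probability, abs=1e-15)


class TestFit:
    def test_parameter_recovery_within_3_se(self, coeffs):
        rng = np.random.default_rng(7)
        true = pc.Coefficients(-3.588, 0.065, 0.185)
        X, y = simulate_cases(true, 2000, rng)
        m = pc.OnsetLogit().fit(X, y)
        z = np.abs((m.params_ - true.as_array()) / m.bse_)
        assert (z < 3.0).all()

    def test_score_vanishes_at_the_estimate(self, coeffs):
        rng = np.random.default_rng(11)
        X, y = simulate_cases(coeffs["alnus"], 300, rng)
        m = pc.OnsetLogit().fit(X, y)
        A = np.column_stack([np.ones(len(y)), X])
        score = A.T @ (y - expit(A @ m.params_))
        assert np.max(np.abs(score)) < 1e-6

    def test_symmetric_balanced_dataset_has_zero_intercept(self):
        # every (x, 1) case mirrored as (-x, 0): flip symmetry forces beta0 = 0
        X = np.random.default_rng(20).normal(0, 1, size=(40, 2))
        Xs = np.vstack([X, -X])
        y = np.array([1] * 40 + [0] * 40)
        m = pc.OnsetLogit().fit(Xs, y)
        assert m.intercept_ == pytest.approx(0.0, abs=1e-7)

    def test_diagnostic_identities(self, coeffs):
        rng = np.random.default_rng(12)
        X, y = simulate_cases(coeffs["corylus"], 400, rng)
        m = pc.OnsetLogit().fit(X, y)
        assert np.allclose(m.odds_ratios_, np.exp(m.params_), rtol=1e-12)
        assert np.allclose(m.wald_chi2_, (m.params_ / m.bse_) ** 2, rtol=1e-12)
        assert np.allclose(m.conf_int_odds_, np.exp(m.conf_int_), rtol=1e-12)
        assert m.lr_chi2_ == pytest.approx(2 * (m.llf_ - m.llnull_), abs=1e-10)
        assert m.lr_chi2_ >= 0
        assert m.df_resid_ == 400 - 3

    def test_agrees_with_statsmodels_oracle(self, coeffs):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(13)
        X, y = simulate_cases(coeffs["alnus"], 500, rng)
        m = pc.OnsetLogit().fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(m.params_, ref.params, atol=1e-7)
        assert np.allclose(m.bse_, ref.bse, atol=1e-7)
        assert m.llf_ == pytest.approx(ref.llf, abs=1e-8)
        assert m.llnull_ == pytest.approx(ref.llnull, abs=1e-6)

    def test_rescaling_equivariance(self, coeffs):
        rng = np.random.default_rng(14)
        X, y = simulate_cases(coeffs["alnus"], 600, rng)
        m = pc.OnsetLogit().fit(X, y)
        mu, sd = X[:, 1].mean(), X[:, 1].std()
        Xs = X.copy()
        Xs[:, 1] = (X[:, 1] - mu) / sd
        ms = pc.OnsetLogit().fit(Xs, y)
        back_t = ms.params_[2] / sd
        back_0 = ms.params_[0] - ms.params_[2] * mu / sd
        assert back_t == pytest.approx(m.params_[2], abs=1e-6)
        assert back_0 == pytest.approx(m.params_[0], abs=1e-6)

    def test_perfect_separation_reported(self):
        X = np.column_stack([np.arange(20.0), np.zeros(20)])
        y = (X[:, 0] > 9.5).astype(int)
        with pytest.raises(SeparationError):
            pc.OnsetLogit().fit(X, y)

    def test_degenerate_inputs_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(ValidationError):
            pc.OnsetLogit().fit(X, np.ones(20))
        with pytest.raises(ValidationError):
            pc.OnsetLogit().fit(X[:5], np.array([0, 1, 0, 1, 0]))

    def test_sklearn_protocol(self, coeffs):
        rng = np.random.default_rng(15)
        X, y = simulate_cases(coeffs["alnus"], 200, rng)
        m = pc.OnsetLogit()
        assert clone(m).get_params() == m.get_params()
        scores = cross_val_score(pc.OnsetLogit(), X, y, cv=3)
        assert scores.shape == (3,) and (scores >= 0).all()
        m.fit(X, y)
        proba = m.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert ((proba[:, 1] > 0.5).astype(int) == m.predict(X)).all()


class TestLRCalibration:
    def test_type_i_error_under_the_null(self):
        # no day/t5 effect: LR chi2(2) p-values should reject ~5% at alpha=.05
        rng = np.random.default_rng(42)
        rejections = 0
        n, reps = 200, 500
        for _ in range(reps):
            X = np.column_stack([rng.uniform(5, 80, n), rng.normal(0, 5, n)])
            y = (rng.random(n) < 0.5).astype(int)
            m = pc.OnsetLogit().fit(X, y)
            rejections += m.lr_pvalue_ < 0.05
        assert 0.03 < rejections / reps < 0.08
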