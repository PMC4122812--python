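"""The two-predictor logistic onset model.

P(onset within the next 10 days) = logistic(β0 + βd·Day + βt·t5), where Day
is the day of year of a detected temperature "local minimum" and t5 the
5-day running-mean temperature on that day. :class:`OnsetLogit` is a
scikit-learn style estimator fitting the model by Newton–Raphson maximum
likelihood and exposing the standard diagnostics: standard errors from the
inverse observed information, t statistics (n−3 residual df), per-parameter
Wald χ², odds ratios e^β with 95% CIs, and the likelihood-ratio χ² against
the intercept-only model (2 df).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ConvergenceError, SeparationError, ValidationError

PREDICTORS = ("day", "t5")
_Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class Coefficients:
    """Onset-model coefficients: intercept, per-day, per-°C."""

    beta0: float
    beta_day: float
    beta_t: float

    def __post_init__(self):
        if not all(np.isfinite([self.beta0, self.beta_day, self.beta_t])):
            raise ValidationError("coefficients must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta_day, self.beta_t], dtype=float)


@dataclass(frozen=True)
class Forecast:
    """A point prediction with the > 0.5 decision."""

    probability: float
    decision: bool  # YES iff probability > 0.5
    day: float
    t5: float


def reference_coefficients(taxon: str) -> Coefficients:
    """Bundled reference coefficient set for ``alnus``, ``corylus`` or ``betula``."""
    payload = json.loads(
        resources.files("pollencast.data")
        .joinpath("reference_coefficients.json")
        .read_text()
    )
    try:
        rec = payload[taxon.lower()]
    except KeyError:
        raise ValidationError(f"no reference coefficients for taxon {taxon!r}")
    return Coefficients(rec["beta0"], rec["beta_day"], rec["beta_t"])


def linear_predictor(c: Coefficients, day, t5):
    return c.beta0 + c.beta_day * np.asarray(day, float) + c.beta_t * np.asarray(t5, float)


def predict(c: Coefficients, day, t5, threshold: float = 0.5):
    """Onset probability (and YES/NO decision) for a local minimum at (day, t5)."""
    day_a, t5_a = np.asarray(day, float), np.asarray(t5, float)
    if not (np.all(np.isfinite(day_a)) and np.all(np.isfinite(t5_a))):
        raise ValidationError("non-finite predictor value")
    p = expit(linear_predictor(c, day_a, t5_a))
    if p.ndim == 0:
        pf = float(p)
        return Forecast(probability=pf, decision=pf > threshold,
                        day=float(day_a), t5=float(t5_a))
    return p


def predict_probability(c: Coefficients, day, t5):
    """Vectorized onset probability (no decision)."""
    return expit(linear_predictor(c, day, t5))


def odds_multiplier(c: Coefficients, predictor: str, delta: float) -> float:
    """Multiplicative change in onset odds for a ``delta`` change in a predictor.

    ``exp(β·delta)`` — e.g. how many times the odds grow over 10 further days,
    or per 5 °C of running-mean warming.
    """
    if predictor not in PREDICTORS:
        raise ValidationError(f"predictor must be one of {PREDICTORS}")
    beta = c.beta_day if predictor == "day" else c.beta_t
    return float(np.exp(beta * delta))


def day_at_probability(c: Coefficients, t5: float, p: float = 0.5) -> float:
    """Day of year at which the onset probability reaches ``p`` at fixed t5.

    Solves β0 + βd·d + βt·t5 = logit(p) in closed form. Round the result to
    the nearest integer for a calendar-day statement.
    """
    if not 0.0 < p < 1.0:
        raise ValidationError("p must lie strictly between 0 and 1")
    if c.beta_day == 0:
        raise ValidationError("beta_day is zero: probability never crosses p in day")
    return float((logit(p) - c.beta0 - c.beta_t * t5) / c.beta_day)


def probability_curve(c: Coefficients, t5: float, days) -> pd.DataFrame:
    """Onset probability as a function of day of year at a fixed temperature."""
    days = np.asarray(days, dtype=float)
    if days.size == 0:
        raise ValidationError("day range is empty")
    return pd.DataFrame({"day": days, "probability": predict_probability(c, days, t5)})


class OnsetLogit(BaseEstimator, ClassifierMixin):
    """Logistic onset model as a scikit-learn classifier.

    Features are ``[day, t5]`` (day of year of a local minimum; running-mean
    temperature on that day); the target is 1 when the pollen season started
    within the forecast window after the minimum. Fitting is plain maximum
    likelihood (no penalty) via Newton–Raphson with step halving.

    Parameters
    ----------
    tol_score : convergence when the max absolute score component drops
        below this.
    tol_params : alternative convergence on the max absolute parameter step.
    max_iter : Newton iteration cap.

    Attributes (after ``fit``)
    --------------------------
    params_ : ndarray (3,) — intercept, day, t5 coefficients.
    bse_ : standard errors (inverse observed information).
    tvalues_, pvalues_t_ : t statistics with ``df_resid_ = n − 3``.
    wald_chi2_, pvalues_wald_ : per-parameter Wald χ² (1 df).
    odds_ratios_, conf_int_, conf_int_odds_ : e^β and 95% CIs.
    llf_, llnull_, lr_chi2_, lr_pvalue_ : log-likelihoods and the LR
        goodness-of-fit test against the intercept-only model (2 df).
    """

    def __init__(self, tol_score: float = 1e-8, tol_params: float = 1e-10,
                 max_iter: int = 100):
        self.tol_score = tol_score
        self.tol_params = tol_params
        self.max_iter = max_iter

    # -- sklearn plumbing ---------------------------------------------------
    def _validate(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            cols = [c for c in PREDICTORS if c in X.columns]
            X = X[cols].to_numpy() if len(cols) == 2 else X.to_numpy()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValidationError("X must have exactly two columns: day, t5")
        if not np.all(np.isfinite(X)):
            raise ValidationError("non-finite predictor value")
        if y is None:
            return X
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(X):
            raise ValidationError("X and y lengths differ")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValidationError("labels must be 0/1")
        return X, y

    def fit(self, X, y):
        X, y = self._validate(X, y)
        n = len(y)
        if n < 10:
            raise ValidationError(f"need at least 10 cases to fit (got {n})")
        if y.min() == y.max():
            raise ValidationError("both labels must be present")
        A = np.column_stack([np.ones(n), X])
        beta = np.zeros(3)
        ll = _loglik(A, y, beta)
        converged = False
        for it in range(1, self.max_iter + 1):
            eta = A @ beta
            p = expit(eta)
            score = A.T @ (y - p)
            if np.max(np.abs(score)) < self.tol_score:
                converged = True
                break
            w = p * (1.0 - p)
            H = A.T @ (A * w[:, None])
            try:
                step = np.linalg.solve(H, score)
            except np.linalg.LinAlgError:
                self._raise_separation_or_singular(A, y, beta)
            # step halving keeps the likelihood non-decreasing
            for _ in range(30):
                cand = beta + step
                ll_new = _loglik(A, y, cand)
                if ll_new >= ll - 1e-12:
                    break
                step = step / 2.0
            beta, ll = cand, ll_new
            if np.max(np.abs(step)) < self.tol_params:
                converged = True
                break
            if np.max(np.abs(A @ beta)) > 30.0 and _separated(A, y, beta):
                raise SeparationError(
                    "perfect separation detected: ML estimates diverge"
                )
        if not converged:
            if _separated(A, y, beta):
                raise SeparationError(
                    "perfect separation detected: ML estimates diverge"
                )
            raise ConvergenceError(f"no convergence in {self.max_iter} iterations")

        eta = A @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        H = A.T @ (A * w[:, None])
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            raise SeparationError("singular information matrix at the optimum")

        self.n_ = n
        self.n_iter_ = it
        self.params_ = beta
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy().reshape(1, 2)
        self.cov_params_ = cov
        self.bse_ = np.sqrt(np.diag(cov))
        self.df_resid_ = n - 3
        self.tvalues_ = beta / self.bse_
        self.pvalues_t_ = 2.0 * stats.t.sf(np.abs(self.tvalues_), self.df_resid_)
        self.wald_chi2_ = (beta / self.bse_) ** 2
        self.pvalues_wald_ = stats.chi2.sf(self.wald_chi2_, 1)
        self.conf_int_ = np.column_stack(
            [beta - _Z975 * self.bse_, beta + _Z975 * self.bse_]
        )
        self.odds_ratios_ = np.exp(beta)
        self.conf_int_odds_ = np.exp(self.conf_int_)
        self.llf_ = float(_loglik(A, y, beta))
        pbar = y.mean()
        self.llnull_ = float(n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))
        self.lr_chi2_ = 2.0 * (self.llf_ - self.llnull_)
        self.lr_df_ = 2
        self.lr_pvalue_ = float(stats.chi2.sf(self.lr_chi2_, self.lr_df_))
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 2
        return self

    def _raise_separation_or_singular(self, A, y, beta):
        if _separated(A, y, beta):
            raise SeparationError("perfect separation detected: ML estimates diverge")
        raise SeparationError("singular information matrix")

    def decision_function(self, X):
        check_is_fitted(self, "params_")
        X = self._validate(X)
        return np.column_stack([np.ones(len(X)), X]) @ self.params_

    def predict_proba(self, X):
        p = expit(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        # strict > 0.5: "the case will happen when its probability is higher than 0.5"
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def to_coefficients(self) -> Coefficients:
        check_is_fitted(self, "params_")
        return Coefficients(*self.params_)

    def summary_frame(self) -> pd.DataFrame:
        """Per-parameter diagnostics table."""
        check_is_fitted(self, "params_")
        return pd.DataFrame(
            {
                "estimate": self.params_,
                "se": self.bse_,
                "t": self.tvalues_,
                "p_t": self.pvalues_t_,
                "wald_chi2": self.wald_chi2_,
                "p_wald": self.pvalues_wald_,
                "odds_ratio": self.odds_ratios_,
                "ci_lower": self.conf_int_[:, 0],
                "ci_upper": self.conf_int_[:, 1],
                "or_ci_lower": self.conf_int_odds_[:, 0],
                "or_ci_upper": self.conf_int_odds_[:, 1],
            },
            index=["intercept", "day", "t5"],
        )


def fit_onset_model(cases) -> OnsetLogit:
    """Fit :class:`OnsetLogit` on a list of training cases (or a frame)."""
    from .training import cases_to_xy  # local import avoids a cycle

    X, y = cases_to_xy(cases)
    return OnsetLogit().fit(X, y)


def _loglik(A, y, beta) -> float:
    eta = A @ beta
    # log-sum-exp form: y*eta - log(1 + e^eta), stable at |eta| ~ hundreds
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _separated(A, y, beta) -> bool:
    eta = A @ beta
    return bool(np.all(eta[y == 1] > 0) and np.all(eta[y == 0] < 0)
                and np.min(np.abs(eta)) > 1e-3)
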