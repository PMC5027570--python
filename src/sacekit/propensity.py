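"""Propensity scores for a binary treatment and a generalized propensity
score (GPS) for time-to-treatment.

The standard score is the fitted probability of treatment from a logistic
regression on baseline covariates.  For the time-of-treatment model the
balancing score is the linear predictor of a Cox proportional-hazards
model for time to treatment (Breslow tie handling); the baseline hazard
is irrelevant for balancing and is not estimated.  Both enter downstream
models as standardized polynomial terms (linear/quadratic/cubic).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from sksurv.linear_model import CoxPHSurvivalAnalysis

from .cohort import DEFAULT_HORIZON_DAYS


def _check_design(X: np.ndarray, names: list[str] | None) -> list[str]:
    X = np.asarray(X, dtype=float)
    names = names or [f"x{j}" for j in range(X.shape[1])]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # point at the first column that does not raise the rank
        bad = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise ValueError(f"design matrix is singular; collinear column(s): {bad}")
    return names


class LogisticPropensityScore(BaseEstimator):
    """Standard propensity score: logistic regression of Z on covariates.

    Parameters
    ----------
    add_intercept : bool
        Prepend an intercept column before fitting (default True).

    Attributes
    ----------
    coef_ : ndarray, named by ``feature_names_``.
    scores_ : fitted treatment probabilities for the training cohort.
    n_iter_ : Newton (IRLS) iterations used.
    """

    def __init__(self, add_intercept: bool = True):
        self.add_intercept = add_intercept

    def _design(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.add_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X

    def fit(self, X, z, feature_names: list[str] | None = None):
        Xd = self._design(X)
        z = np.asarray(z, dtype=float)
        if feature_names is not None and self.add_intercept:
            feature_names = ["intercept"] + list(feature_names)
        self.feature_names_ = _check_design(Xd, feature_names)
        with np.errstate(all="ignore"):
            res = sm.Logit(z, Xd).fit(disp=0, maxiter=200)
        self.coef_ = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(self.coef_)) or np.abs(self.coef_).max() > 50:
            raise ValueError(
                "logistic propensity model appears separated (diverging "
                "coefficients); review the covariate set"
            )
        self.scores_ = np.asarray(res.predict(Xd), dtype=float)
        retvals = getattr(res, "mle_retvals", {}) or {}
        self.n_iter_ = int(retvals.get("iterations", 0))
        self.result_ = res
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        lp = self._design(X) @ self.coef_
        p = 1.0 / (1.0 + np.exp(-lp))
        return np.column_stack([1 - p, p])

    def score_samples(self, X):
        """Propensity scores (treatment probabilities) for new subjects."""
        return self.predict_proba(X)[:, 1]


class CoxGPS(BaseEstimator):
    """Generalized propensity score: Cox PH linear predictor for time to
    treatment.

    Untreated subjects contribute censored times: ``min(death day,
    horizon)`` by default; subjects treated after the horizon are
    censored at the horizon.  Ties are handled by Breslow's method.

    Attributes
    ----------
    coef_ : partial-likelihood estimates (no intercept; a Cox model has
        none).
    scores_ : linear predictors D_i' beta for the training cohort.
    degenerate_ : True when every covariate is constant, in which case
        the partial likelihood is flat and coefficients are zero.
    """

    def __init__(self, horizon_days: int = DEFAULT_HORIZON_DAYS):
        self.horizon_days = horizon_days

    def fit(self, X, time, event, feature_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=bool)
        if not np.any(event):
            raise ValueError("no treatment events; cannot fit the Cox GPS model")
        if np.any(time <= 0):
            raise ValueError("times must be positive")
        self.feature_names_ = feature_names or [f"x{j}" for j in range(X.shape[1])]
        self.degenerate_ = bool(np.all(np.ptp(X, axis=0) == 0))
        if self.degenerate_:
            self.coef_ = np.zeros(X.shape[1])
            self.scores_ = X @ self.coef_
            return self
        _check_design(X, self.feature_names_)
        y = np.empty(len(time), dtype=[("event", "?"), ("time", "f8")])
        y["event"], y["time"] = event, time
        model = CoxPHSurvivalAnalysis(ties="breslow", n_iter=200, tol=1e-10)
        try:
            model.fit(X, y)
        except (ValueError, ArithmeticError) as exc:
            raise ValueError(
                f"Cox GPS fit failed (possibly monotone likelihood): {exc}"
            ) from exc
        self.coef_ = np.asarray(model.coef_, dtype=float)
        if not np.all(np.isfinite(self.coef_)):
            raise ValueError("non-finite Cox coefficients (monotone likelihood?)")
        self.scores_ = X @ self.coef_
        return self

    def score_samples(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_


def gps_times(
    df: pd.DataFrame, horizon_days: int = DEFAULT_HORIZON_DAYS,
    censor_untreated_at: str = "death_or_horizon",
) -> tuple[np.ndarray, np.ndarray]:
    """Build (time, event) pairs for the time-to-treatment Cox model.

    Treated within the horizon: event at the treatment day.  Untreated:
    censored at min(death day, horizon) (default) or at the horizon
    (``censor_untreated_at='horizon'``).
    """
    n = len(df)
    time = np.full(n, float(horizon_days))
    event = df["Z"].to_numpy() == 1
    t_day = df["treatment_day"].to_numpy(dtype=float)
    time[event] = t_day[event]
    if censor_untreated_at == "death_or_horizon" and "death_day" in df.columns:
        d = df["death_day"].to_numpy(dtype=float)
        untreated = ~event
        time[untreated] = np.fmin(d[untreated], horizon_days)
    time = np.maximum(time, 0.5)  # day-0 treatments still carry risk time
    return time, event


def fit_logistic_ps(X, z, feature_names=None) -> LogisticPropensityScore:
    return LogisticPropensityScore().fit(X, z, feature_names=feature_names)


def fit_cox_gps(X, time, event, feature_names=None) -> CoxGPS:
    return CoxGPS().fit(X, time, event, feature_names=feature_names)


def expand_ps_terms(scores: np.ndarray, order: int) -> np.ndarray:
    """Standardize the score and return [s, s^2, ..., s^order] columns.

    Raw polynomials on the standardized score; standardization is for
    numerical stability only.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    s = np.asarray(scores, dtype=float)
    sd = s.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("scores are constant; no variation to adjust for")
    s = (s - s.mean()) / sd
    return np.column_stack([s**k for k in range(1, order + 1)])


def balance_table(
    df: pd.DataFrame,
    covariates: list[str],
    ps_terms: np.ndarray | None,
    gps_terms: np.ndarray | None,
    binary_covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Covariate balance before and after propensity adjustment.

    For each covariate, regress it on the treatment indicator alone,
    then with standard-PS terms, then with GPS terms, and report the
    p-value of the treatment coefficient (linear regression for
    continuous covariates, logistic for binary ones).  Small p-values
    flag residual association of the covariate with treatment.
    """
    z = df["Z"].to_numpy(dtype=float)
    binary_covariates = set(binary_covariates or [])
    out = []
    for name in covariates:
        x = df[name].to_numpy(dtype=float)
        row = {"covariate": name}
        for label, terms in (
            ("marginal", None),
            ("standard_ps", ps_terms),
            ("gps", gps_terms),
        ):
            if terms is None and label != "marginal":
                row[f"p_{label}"] = np.nan
                continue
            design = np.column_stack(
                [np.ones_like(z), z] + ([terms] if terms is not None else [])
            )
            try:
                if name in binary_covariates:
                    res = sm.Logit(x, design).fit(disp=0, maxiter=200)
                else:
                    res = sm.OLS(x, design).fit()
                p = float(res.pvalues[1])
            except Exception:
                p = np.nan
            # a covariate with no variation cannot be associated with Z
            if np.ptp(x) == 0:
                p = 1.0
            row[f"p_{label}"] = p
        out.append(row)
    return pd.DataFrame(out)
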