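"""Estimator-style front end for the full SACE pipeline.

``PrincipalStratificationSACE`` bundles propensity fitting, polynomial
term expansion, and the data-augmentation MCMC behind a scikit-learn
style ``fit`` so model variants compose with standard tooling
(``get_params``/``set_params``, ``clone``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import effects as ef
from . import propensity as ps
from . import sampler as sp


class PrincipalStratificationSACE(BaseEstimator):
    """Survivor average causal effect under censoring by death.

    Fits a Bayesian principal-stratification mixture to a derived
    cohort frame (columns ``Z``, ``S``, ``Y``,
    ``time_from_treatment_months``, plus covariates): a multinomial
    logit for stratum membership and per-stratum normal outcome
    regressions, with a standard propensity score (binary treatment
    model) or a Cox generalized propensity score (time-of-treatment
    model) entering both as polynomial adjustment terms.  Sampling is by
    data augmentation: stratum imputation alternating with conjugate
    Gibbs and Metropolis parameter updates.

    Parameters
    ----------
    covariates : list of str
        Covariate columns for the propensity model (assumed already
        standardized where continuous).
    model_type : 'binary' | 'time'
        Treatment defined as an indicator only, or indicator plus
        months from treatment to the horizon.
    ps_order : 0..3
        Number of polynomial propensity terms (0 = no adjustment).
    monotonicity : bool
        Assume treatment cannot cause otherwise-avoided death (drops
        the DL stratum).
    n_iter, burn_in : int
        MCMC length; posterior summaries use the post-burn-in draws.
    random_state : int
        Seed for the single generator driving the whole chain.

    Attributes
    ----------
    ps_model_ : the fitted propensity model.
    draws_ : PosteriorDraws with all retained chains.
    sace_ : SaceSummary of the treatment term(s).
    """

    def __init__(
        self,
        covariates: list[str] | None = None,
        model_type: str = "binary",
        ps_order: int = 1,
        monotonicity: bool = False,
        n_iter: int = 10_000,
        burn_in: int = 5_000,
        random_state: int = 0,
        prior_scale: float = 100.0,
        prior_a0: float = 2.0,
        prior_b0: float = 4.0,
        horizon_days: int = 365,
        censor_untreated_at: str = "death_or_horizon",
    ):
        self.covariates = covariates
        self.model_type = model_type
        self.ps_order = ps_order
        self.monotonicity = monotonicity
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.random_state = random_state
        self.prior_scale = prior_scale
        self.prior_a0 = prior_a0
        self.prior_b0 = prior_b0
        self.horizon_days = horizon_days
        self.censor_untreated_at = censor_untreated_at

    def fit(self, df: pd.DataFrame, y=None):
        if self.model_type not in ("binary", "time"):
            raise ValueError("model_type must be 'binary' or 'time'")
        if self.ps_order not in (0, 1, 2, 3):
            raise ValueError("ps_order must be in 0..3")
        covs = self.covariates or []
        X = df[covs].to_numpy(dtype=float) if covs else None
        if self.ps_order > 0 and X is None:
            raise ValueError("ps_order > 0 requires covariates")
        self.ps_terms_ = None
        self.ps_model_ = None
        if self.ps_order > 0:
            if self.model_type == "time":
                time, event = ps.gps_times(
                    df, self.horizon_days, self.censor_untreated_at
                )
                self.ps_model_ = ps.CoxGPS(self.horizon_days).fit(
                    X, time, event, feature_names=covs
                )
            else:
                self.ps_model_ = ps.LogisticPropensityScore().fit(
                    X, df["Z"].to_numpy(), feature_names=covs
                )
            self.ps_terms_ = ps.expand_ps_terms(self.ps_model_.scores_, self.ps_order)
        self.data_ = sp.prepare_model_data(
            df, self.model_type, self.ps_terms_, self.monotonicity
        )
        priors = sp.default_priors(
            self.data_, scale=self.prior_scale, a0=self.prior_a0, b0=self.prior_b0
        )
        cfg = sp.SamplerConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            seed=self.random_state,
            model_type=self.model_type,
            monotonicity=self.monotonicity,
            ps_order=self.ps_order,
        )
        self.draws_ = sp.run_da_mcmc(self.data_, priors=priors, config=cfg)
        self.sace_ = ef.compute_sace(self.draws_)
        return self

    def sace_summary(self) -> pd.DataFrame:
        check_is_fitted(self, "sace_")
        return self.sace_.to_frame()

    def effect_curve(self, delta_grid: np.ndarray | None = None) -> ef.EffectCurve:
        check_is_fitted(self, "draws_")
        return ef.effect_curve(self.draws_, delta_grid)

    def diagnostics(self) -> dict:
        check_is_fitted(self, "draws_")
        return sp.diagnostics(self.draws_)
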