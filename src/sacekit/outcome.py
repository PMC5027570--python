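"""Per-stratum normal outcome regressions with conjugate priors.

Survivors' outcomes are modeled as Y ~ N(X1' eta_g, sigma2_g) within
each stratum that can contain an observed outcome (LL, LD, DL).  The
always-survivor (LL) design carries the treatment columns — a binary
indicator and, in the time-of-treatment model, months from treatment to
the horizon — while LD and DL designs carry only the intercept and the
propensity terms (their observed members are all treated or all
untreated, so treatment columns would be constant).  DD members never
contribute an outcome and have no outcome model.

Conjugate multivariate-normal / inverse-gamma priors give closed-form
Gibbs updates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .strata import DD, LL

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class NormalInvGammaPrior:
    """eta ~ MVN(mu0, Sigma0), sigma2 ~ InvGamma(a0, b0)."""

    mu0: np.ndarray
    Sigma0: np.ndarray
    a0: float = 2.0
    b0: float = 4.0

    @classmethod
    def default(cls, dim: int, scale: float = 100.0, a0: float = 2.0, b0: float = 4.0):
        """Weakly informative conjugate default on standardized covariates."""
        return cls(mu0=np.zeros(dim), Sigma0=scale * np.eye(dim), a0=a0, b0=b0)

    @property
    def Sigma0_inv(self) -> np.ndarray:
        return np.linalg.inv(self.Sigma0)


@dataclass
class OutcomeParameters:
    """Current regression coefficients and variances, one set per
    outcome-bearing stratum."""

    eta: dict[int, np.ndarray]
    sigma2: dict[int, float]


def stratum_design(
    Z: np.ndarray,
    time_months: np.ndarray,
    ps_terms: np.ndarray | None,
    stratum: int,
    model_type: str = "binary",
) -> np.ndarray:
    """Build the outcome design matrix X1 for a stratum.

    LL, binary model: [1, Z, PS terms]; LL, time model:
    [1, Z, Z*(months from treatment to horizon), GPS terms];
    LD/DL: [1, PS terms].
    """
    if stratum == DD:
        raise ValueError("the DD stratum has no observable outcomes, hence no design")
    if model_type not in ("binary", "time"):
        raise ValueError("model_type must be 'binary' or 'time'")
    Z = np.asarray(Z, dtype=float)
    n = len(Z)
    cols = [np.ones(n)]
    if stratum == LL:
        cols.append(Z)
        if model_type == "time":
            cols.append(Z * np.asarray(time_months, dtype=float))
    if ps_terms is not None and np.size(ps_terms):
        cols.append(np.atleast_2d(np.asarray(ps_terms, dtype=float).T).T)
    return np.column_stack(cols)


def design_names(stratum: int, model_type: str, ps_order: int, score_label: str = "ps") -> list[str]:
    names = ["intercept"]
    if stratum == LL:
        names.append("Z")
        if model_type == "time":
            names.append("time_from_treatment_months")
    names += [f"{score_label}^{k}" for k in range(1, ps_order + 1)]
    return names


def normal_logdensity(y, mean, sigma2) -> np.ndarray:
    """Elementwise log N(y | mean, sigma2)."""
    if np.any(np.asarray(sigma2) <= 0):
        raise ValueError("sigma2 must be positive")
    r = np.asarray(y, dtype=float) - np.asarray(mean, dtype=float)
    return -0.5 * (_LOG2PI + np.log(sigma2) + r * r / sigma2)


def gibbs_update_eta(
    X: np.ndarray,
    y: np.ndarray,
    sigma2: float,
    prior: NormalInvGammaPrior,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw eta | y, sigma2 from MVN(V m, V),
    V = (X'X/sigma2 + Sigma0^-1)^-1, m = X'y/sigma2 + Sigma0^-1 mu0.

    With no members the draw reduces to the prior.  The proper prior
    regularizes any rank deficiency in X.
    """
    P0 = prior.Sigma0_inv
    if len(y) == 0:
        prec = P0
        m = P0 @ prior.mu0
    else:
        prec = X.T @ X / sigma2 + P0
        m = X.T @ y / sigma2 + P0 @ prior.mu0
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, m)
    # solve L' u = z gives a draw with covariance prec^-1
    z = rng.standard_normal(len(m))
    return mean + np.linalg.solve(L.T, z)


def gibbs_update_sigma2(
    residuals: np.ndarray, prior: NormalInvGammaPrior, rng: np.random.Generator
) -> float:
    """Draw sigma2 | residuals from InvGamma(a0 + n/2, b0 + RSS/2)."""
    n = len(residuals)
    a = prior.a0 + 0.5 * n
    b = prior.b0 + 0.5 * float(np.dot(residuals, residuals))
    # tiny shapes (empty stratum, diffuse prior) can underflow to 0.0
    return float(b / max(rng.gamma(a), 1e-290))
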