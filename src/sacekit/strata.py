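"""Principal strata for survival truncated ("censored") by death.

Each subject belongs to a latent stratum defined by the pair of
potential survival statuses (S(1), S(0)) at the horizon:

* ``LL`` — alive under either treatment choice (the always-survivors;
  the only stratum in which a treated-vs-untreated outcome contrast is
  well defined, hence the SACE stratum);
* ``LD`` — alive only if treated;
* ``DL`` — alive only if untreated;
* ``DD`` — dies under either choice.

The observed (Z, S) group identifies a mixture of exactly two strata;
stratum probabilities follow a multinomial logit on a design that
includes the (generalized) propensity score, with DD as the reference
category.  Under the monotonicity assumption (treatment cannot cause a
death that would not otherwise occur) the DL stratum is empty, and two
of the observed groups become pure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

LL, LD, DL, DD = 0, 1, 2, 3
STRATUM_LABELS = ("LL", "LD", "DL", "DD")

#: observed group (Z, S) -> tuple of compatible strata
COMPATIBLE = {
    (1, 1): (LL, LD),
    (1, 0): (DL, DD),
    (0, 1): (LL, DL),
    (0, 0): (LD, DD),
}
COMPATIBLE_MONOTONE = {
    (1, 1): (LL, LD),
    (1, 0): (DD,),
    (0, 1): (LL,),
    (0, 0): (LD, DD),
}


def active_strata(monotonicity: bool) -> tuple[int, ...]:
    return (LL, LD, DD) if monotonicity else (LL, LD, DL, DD)


def stratum_survival(g: int, z: int) -> int:
    """Survival status implied by stratum g under treatment choice z."""
    return {LL: (1, 1), LD: (0, 1), DL: (1, 0), DD: (0, 0)}[g][z]


@dataclass
class StrataParameters:
    """Multinomial-logit coefficients, one vector per non-reference
    stratum; the reference stratum (DD) is fixed at zero."""

    alpha: dict[int, np.ndarray]
    monotonicity: bool = False
    reference: int = DD

    @property
    def non_reference(self) -> tuple[int, ...]:
        return tuple(g for g in active_strata(self.monotonicity) if g != self.reference)

    @classmethod
    def zeros(cls, n_features: int, monotonicity: bool = False) -> "StrataParameters":
        strata = active_strata(monotonicity)
        return cls(
            alpha={g: np.zeros(n_features) for g in strata if g != DD},
            monotonicity=monotonicity,
        )

    def stack(self) -> np.ndarray:
        """Coefficients as a (n_features, n_active) matrix, reference
        column zero, columns ordered by :func:`active_strata`."""
        strata = active_strata(self.monotonicity)
        p = len(next(iter(self.alpha.values())))
        A = np.zeros((p, len(strata)))
        for j, g in enumerate(strata):
            if g != self.reference:
                A[:, j] = self.alpha[g]
        return A


def observed_group(z: int, s: int, monotonicity: bool = False) -> tuple[str, tuple[int, ...]]:
    """Map realized (Z, S) to the observed group label and the set of
    principal strata it can contain."""
    if z not in (0, 1) or s not in (0, 1):
        raise ValueError("Z and S must be 0/1")
    table = COMPATIBLE_MONOTONE if monotonicity else COMPATIBLE
    return f"O({z},{s})", table[(z, s)]


def strata_log_probs(params: StrataParameters, X2: np.ndarray) -> np.ndarray:
    """Log stratum probabilities, (n, n_active), columns ordered by
    :func:`active_strata`; softmax of X2 @ alpha with the reference at 0."""
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    lp = X2 @ params.stack()
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictor in the strata model")
    return lp - logsumexp(lp, axis=1, keepdims=True)


def strata_probs(params: StrataParameters, x2: np.ndarray) -> np.ndarray:
    """Stratum membership probabilities pi for one design row (or a
    matrix of rows); rows sum to one."""
    pi = np.exp(strata_log_probs(params, x2))
    return pi[0] if np.asarray(x2).ndim == 1 else pi


def membership_log_weights(
    z: int,
    s: int,
    log_pi: np.ndarray,
    log_f: dict[int, float] | None,
    monotonicity: bool = False,
) -> tuple[tuple[int, ...], np.ndarray]:
    """Unnormalized log conditional-membership weights for one subject.

    For survivors the weight of stratum g is log pi_g + log f_g(Y|X);
    for subjects who die before the horizon the outcome is undefined and
    only log pi_g contributes.  Incompatible strata carry no mass.
    """
    _, compat = observed_group(z, s, monotonicity)
    strata = active_strata(monotonicity)
    idx = {g: j for j, g in enumerate(strata)}
    w = np.array([log_pi[idx[g]] for g in compat], dtype=float)
    if s == 1:
        if log_f is None:
            raise ValueError("survivor requires outcome log-densities")
        w = w + np.array([log_f[g] for g in compat])
    return compat, w


def membership_probs(
    z: int,
    s: int,
    log_pi: np.ndarray,
    log_f: dict[int, float] | None = None,
    monotonicity: bool = False,
) -> np.ndarray:
    """Conditional stratum-membership probabilities rho for one subject,
    as a length-4 vector over (LL, LD, DL, DD); exactly zero outside the
    compatible set."""
    compat, w = membership_log_weights(z, s, log_pi, log_f, monotonicity)
    w = np.exp(w - logsumexp(w))
    rho = np.zeros(4)
    for g, p in zip(compat, w):
        rho[g] = p
    return rho


def loglik_alpha(
    params: StrataParameters, X2: np.ndarray, labels: np.ndarray
) -> float:
    """Complete-data log-likelihood of the multinomial-logit coefficients
    given imputed stratum labels (the Metropolis target under a flat
    prior)."""
    logp = strata_log_probs(params, X2)
    strata = active_strata(params.monotonicity)
    idx = {g: j for j, g in enumerate(strata)}
    cols = np.array([idx[g] for g in labels])
    return float(logp[np.arange(len(labels)), cols].sum())
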