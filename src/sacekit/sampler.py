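"""Data-augmentation MCMC for the principal-stratification mixture.

The observed-data likelihood is a two-component mixture within each
observed (Z, S) group (each group can contain exactly two principal
strata).  The sampler alternates:

* I-step — impute each subject's stratum label from its conditional
  membership probabilities (mixture-cell ratios) at the current
  parameters; survivors weight the stratum probability by the stratum's
  outcome density, non-survivors by the stratum probability alone;
* P-step — given the completed data, conjugate Gibbs draws for each
  stratum's regression coefficients and variance, and a blockwise
  random-walk Metropolis update for the multinomial-logit coefficients
  (weak Gaussian prior by default; flat on request), one Gaussian
  proposal per non-reference stratum.

Proposal step sizes are adapted toward 0.3 acceptance during burn-in
(Robbins-Monro) and frozen afterwards to preserve the Markov property.
All randomness flows from one seeded generator, with subjects processed
in a fixed order, so chains are bit-reproducible from the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import outcome as oc
from . import strata as st
from .outcome import NormalInvGammaPrior, OutcomeParameters
from .strata import DD, DL, LD, LL, StrataParameters, active_strata


@dataclass
class SamplerConfig:
    n_iter: int = 10_000
    burn_in: int = 5_000
    seed: int = 0
    mh_step_size: float = 0.25
    adapt_during_burnin: bool = True
    model_type: str = "binary"
    monotonicity: bool = False
    ps_order: int = 1
    target_acceptance: float = 0.3
    #: sd of the Gaussian prior on each logit coefficient; None = flat.
    #: A proper (if weak) prior keeps the chain irreducible: with a flat
    #: prior, a sparse stratum that empties during imputation leaves its
    #: alpha block a monotone likelihood, the block drifts off to -inf,
    #: and the stratum can never be repopulated.
    alpha_prior_sd: float | None = 5.0
    max_step_size: float = 25.0

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.mh_step_size <= 0:
            raise ValueError("step sizes must be positive")


@dataclass
class ModelData:
    """Arrays the sampler iterates over, built once per fit."""

    Z: np.ndarray
    S: np.ndarray
    Y: np.ndarray
    time_months: np.ndarray
    X2: np.ndarray                      # strata-model design (incl. intercept)
    X1: dict[int, np.ndarray]           # outcome designs per stratum
    monotonicity: bool
    model_type: str

    @property
    def n(self) -> int:
        return len(self.Z)

    @property
    def groups(self) -> dict[tuple[int, int], np.ndarray]:
        return {
            (z, s): np.flatnonzero((self.Z == z) & (self.S == s))
            for z in (0, 1)
            for s in (0, 1)
        }


def prepare_model_data(
    df,
    model_type: str = "binary",
    ps_terms: np.ndarray | None = None,
    monotonicity: bool = False,
    x2_extra: np.ndarray | None = None,
) -> ModelData:
    """Assemble sampler arrays from a derived cohort frame.

    ``ps_terms`` are the standardized polynomial propensity columns
    (standard PS for the binary model, GPS for the time model); the
    strata design X2 is [intercept, ps_terms, x2_extra].
    """
    Z = df["Z"].to_numpy(dtype=int)
    S = df["S"].to_numpy(dtype=int)
    Y = df["Y"].to_numpy(dtype=float)
    Tm = df["time_from_treatment_months"].to_numpy(dtype=float)
    n = len(Z)
    blocks = [np.ones((n, 1))]
    if ps_terms is not None and np.size(ps_terms):
        blocks.append(np.atleast_2d(np.asarray(ps_terms, dtype=float).T).T)
    if x2_extra is not None and np.size(x2_extra):
        blocks.append(np.atleast_2d(np.asarray(x2_extra, dtype=float).T).T)
    X2 = np.column_stack(blocks)
    X1 = {
        g: oc.stratum_design(Z, Tm, ps_terms, g, model_type)
        for g in (LL, LD, DL)
    }
    return ModelData(
        Z=Z, S=S, Y=Y, time_months=Tm, X2=X2, X1=X1,
        monotonicity=monotonicity, model_type=model_type,
    )


def default_priors(data: ModelData, scale: float = 100.0,
                   a0: float = 2.0, b0: float = 4.0) -> dict[int, NormalInvGammaPrior]:
    return {
        g: NormalInvGammaPrior.default(data.X1[g].shape[1], scale=scale, a0=a0, b0=b0)
        for g in (LL, LD, DL)
    }


@dataclass
class PosteriorDraws:
    """Post-burn-in chains plus bookkeeping for one sampler run."""

    eta: dict[int, np.ndarray]          # (n_keep, p_g) per stratum
    sigma2: dict[int, np.ndarray]       # (n_keep,) per stratum
    alpha: dict[int, np.ndarray]        # (n_keep, p2) per non-reference stratum
    strata_counts: np.ndarray           # (n_keep, 4) in (LL, LD, DL, DD) order
    acceptance: dict[int, float]
    config: SamplerConfig
    step_sizes: dict[int, float] = field(default_factory=dict)
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_keep(self) -> int:
        return len(self.strata_counts)

    def treatment_chains(self) -> dict[str, np.ndarray]:
        """Chains of the LL treatment coefficients: the SACE parameters."""
        out = {"Z": self.eta[LL][:, 1]}
        if self.config.model_type == "time":
            out["time_from_treatment_months"] = self.eta[LL][:, 2]
        return out


def _uniform_compatible(z, s, monotonicity, rng):
    _, compat = st.observed_group(z, s, monotonicity)
    return compat[rng.integers(len(compat))] if len(compat) > 1 else compat[0]


def initialize_state(
    data: ModelData, config: SamplerConfig, rng: np.random.Generator
) -> tuple[np.ndarray, StrataParameters, OutcomeParameters]:
    """Starting point: uniform stratum draws over each subject's
    compatible set, alpha = 0, per-stratum OLS (ridge-stabilized)
    coefficients with residual variances (fallback zeros / 1)."""
    G = np.array(
        [
            _uniform_compatible(z, s, data.monotonicity, rng)
            for z, s in zip(data.Z, data.S)
        ]
    )
    alpha = StrataParameters.zeros(data.X2.shape[1], data.monotonicity)
    eta, sigma2 = {}, {}
    for g in (LL, LD, DL):
        mask = (data.S == 1) & (G == g)
        X, y = data.X1[g][mask], data.Y[mask]
        p = X.shape[1]
        if mask.sum() > p:
            coef, *_ = np.linalg.lstsq(
                np.vstack([X, 1e-4 * np.eye(p)]), np.concatenate([y, np.zeros(p)]),
                rcond=None,
            )
            resid = y - X @ coef
            s2 = float(resid @ resid / max(len(y) - p, 1))
            eta[g], sigma2[g] = coef, max(s2, 1e-6)
        else:
            eta[g], sigma2[g] = np.zeros(p), 1.0
    return G, alpha, OutcomeParameters(eta=eta, sigma2=sigma2)


def _survivor_logf(data: ModelData, params: OutcomeParameters, idx: np.ndarray,
                   g: int) -> np.ndarray:
    X = data.X1[g][idx]
    return oc.normal_logdensity(data.Y[idx], X @ params.eta[g], params.sigma2[g])


def i_step(
    data: ModelData,
    alpha: StrataParameters,
    outcome_params: OutcomeParameters,
    rng: np.random.Generator,
    log_pi: np.ndarray | None = None,
) -> np.ndarray:
    """Impute stratum labels: one categorical draw per subject over its
    compatible strata, with Table-row-ratio probabilities."""
    if log_pi is None:
        log_pi = st.strata_log_probs(alpha, data.X2)
    strata = active_strata(data.monotonicity)
    col = {g: j for j, g in enumerate(strata)}
    G = np.empty(data.n, dtype=int)
    groups = data.groups
    u = rng.random(data.n)  # one uniform per subject, fixed order

    def bern(idx, gA, gB, wA, wB):
        pA = 1.0 / (1.0 + np.exp(np.clip(wB - wA, -700, 700)))
        G[idx] = np.where(u[idx] < pA, gA, gB)

    idx = groups[(1, 1)]  # survivors, treated: LL vs LD
    if len(idx):
        bern(
            idx, LL, LD,
            log_pi[idx, col[LL]] + _survivor_logf(data, outcome_params, idx, LL),
            log_pi[idx, col[LD]] + _survivor_logf(data, outcome_params, idx, LD),
        )
    idx = groups[(0, 1)]  # survivors, untreated: LL vs DL (LL if monotone)
    if len(idx):
        if data.monotonicity:
            G[idx] = LL
        else:
            bern(
                idx, LL, DL,
                log_pi[idx, col[LL]] + _survivor_logf(data, outcome_params, idx, LL),
                log_pi[idx, col[DL]] + _survivor_logf(data, outcome_params, idx, DL),
            )
    idx = groups[(1, 0)]  # deaths, treated: DL vs DD (DD if monotone)
    if len(idx):
        if data.monotonicity:
            G[idx] = DD
        else:
            bern(idx, DL, DD, log_pi[idx, col[DL]], log_pi[idx, col[DD]])
    idx = groups[(0, 0)]  # deaths, untreated: LD vs DD
    if len(idx):
        bern(idx, LD, DD, log_pi[idx, col[LD]], log_pi[idx, col[DD]])
    return G


def _loglik_from_lp(Lp: np.ndarray, cols: np.ndarray) -> float:
    m = Lp.max(axis=1)
    lse = m + np.log(np.exp(Lp - m[:, None]).sum(axis=1))
    return float(Lp[np.arange(len(cols)), cols].sum() - lse.sum())


def p_step(
    data: ModelData,
    G: np.ndarray,
    alpha: StrataParameters,
    outcome_params: OutcomeParameters,
    priors: dict[int, NormalInvGammaPrior],
    step_sizes: dict[int, float],
    rng: np.random.Generator,
    alpha_prior_sd: float | None = 5.0,
) -> tuple[StrataParameters, OutcomeParameters, dict[int, bool], np.ndarray]:
    """Posterior step on the completed data.

    Gibbs for (eta_g, sigma2_g) over survivors imputed to each stratum;
    blockwise random-walk Metropolis for the logit coefficients.
    Returns updated parameters, per-block acceptance indicators, and the
    log stratum probabilities at the accepted alpha (reused by the next
    I-step).
    """
    eta, sigma2 = {}, {}
    for g in (LL, LD, DL):
        mask = (data.S == 1) & (G == g)
        X, y = data.X1[g][mask], data.Y[mask]
        eta[g] = oc.gibbs_update_eta(X, y, outcome_params.sigma2[g], priors[g], rng)
        resid = y - X @ eta[g] if len(y) else y
        sigma2[g] = oc.gibbs_update_sigma2(resid, priors[g], rng)
    new_outcome = OutcomeParameters(eta=eta, sigma2=sigma2)

    strata = active_strata(data.monotonicity)
    col = {g: j for j, g in enumerate(strata)}
    cols = np.fromiter((col[g] for g in G), dtype=int, count=len(G))
    A = alpha.stack()                        # (p2, K)
    Lp = data.X2 @ A
    cur = _loglik_from_lp(Lp, cols)
    new_alpha = {g: alpha.alpha[g].copy() for g in alpha.alpha}
    accepted = {}

    def log_prior(v):
        if alpha_prior_sd is None:
            return 0.0
        return float(-0.5 * np.dot(v, v) / alpha_prior_sd**2)

    for g in alpha.non_reference:
        j = col[g]
        prop = new_alpha[g] + step_sizes[g] * rng.standard_normal(data.X2.shape[1])
        Lp_j, Lp[:, j] = Lp[:, j].copy(), data.X2 @ prop
        cand = _loglik_from_lp(Lp, cols)
        cur_post = cur + log_prior(new_alpha[g])
        cand_post = cand + log_prior(prop)
        if np.isfinite(cand_post) and np.log(rng.random()) < cand_post - cur_post:
            new_alpha[g], cur, accepted[g] = prop, cand, True
        else:
            Lp[:, j] = Lp_j
            accepted[g] = False
    out_params = StrataParameters(
        alpha=new_alpha, monotonicity=alpha.monotonicity, reference=alpha.reference
    )
    # normalized log stratum probabilities at the accepted alpha
    m = Lp.max(axis=1, keepdims=True)
    log_pi = Lp - (m + np.log(np.exp(Lp - m).sum(axis=1, keepdims=True)))
    return out_params, new_outcome, accepted, log_pi


def run_da_mcmc(
    data: ModelData,
    priors: dict[int, NormalInvGammaPrior] | None = None,
    config: SamplerConfig | None = None,
    clamp_strata: np.ndarray | None = None,
) -> PosteriorDraws:
    """Run the full data-augmentation sampler.

    ``clamp_strata`` fixes the stratum labels (skipping the I-step),
    which reduces the sampler to conjugate Gibbs + Metropolis on a
    complete dataset — used for oracle checks and debugging.

    Internally the outcome is centered at its survivor mean so that the
    zero-centered coefficient priors sit on the data scale (an exact
    reparameterization; intercept chains are shifted back before they
    are returned).  Without this, a stratum that empties draws its
    coefficients from the raw prior, its density at any real outcome is
    negligible, and the empty state becomes absorbing.
    """
    config = config or SamplerConfig()
    priors = priors or default_priors(data)
    rng = np.random.default_rng(config.seed)
    y_center = float(np.nanmean(data.Y[data.S == 1])) if np.any(data.S == 1) else 0.0
    data = replace(data, Y=data.Y - y_center)
    G, alpha, outcome_params = initialize_state(data, config, rng)
    if clamp_strata is not None:
        G = np.asarray(clamp_strata, dtype=int).copy()
    step_sizes = {g: config.mh_step_size for g in alpha.non_reference}
    n_keep = config.n_iter - config.burn_in
    keep_eta = {g: np.empty((n_keep, data.X1[g].shape[1])) for g in (LL, LD, DL)}
    keep_s2 = {g: np.empty(n_keep) for g in (LL, LD, DL)}
    keep_alpha = {g: np.empty((n_keep, data.X2.shape[1])) for g in alpha.non_reference}
    counts = np.empty((n_keep, 4), dtype=int)
    acc_total = {g: 0 for g in alpha.non_reference}
    log_pi = None
    for k in range(config.n_iter):
        if clamp_strata is None:
            G = i_step(data, alpha, outcome_params, rng, log_pi=log_pi)
        alpha, outcome_params, accepted, log_pi = p_step(
            data, G, alpha, outcome_params, priors, step_sizes, rng,
            alpha_prior_sd=config.alpha_prior_sd,
        )
        if k < config.burn_in and config.adapt_during_burnin:
            gamma = min(0.25, 2.0 / np.sqrt(k + 10))
            for g, acc in accepted.items():
                step_sizes[g] = min(
                    config.max_step_size,
                    step_sizes[g]
                    * np.exp(gamma * ((1.0 if acc else 0.0) - config.target_acceptance)),
                )
        if k >= config.burn_in:
            j = k - config.burn_in
            for g in (LL, LD, DL):
                keep_eta[g][j] = outcome_params.eta[g]
                keep_s2[g][j] = outcome_params.sigma2[g]
            for g in keep_alpha:
                keep_alpha[g][j] = alpha.alpha[g]
            counts[j] = np.bincount(G, minlength=4)
            for g, acc in accepted.items():
                acc_total[g] += int(acc)
    for g in (LL, LD, DL):
        keep_eta[g][:, 0] += y_center
    rates = {g: acc_total[g] / n_keep for g in acc_total}
    warns = [
        f"MH acceptance rate for stratum {st.STRATUM_LABELS[g]} is "
        f"{r:.2f}, outside [0.05, 0.8]"
        for g, r in rates.items()
        if not 0.05 <= r <= 0.8
    ]
    for w in warns:
        warnings.warn(w, stacklevel=2)
    return PosteriorDraws(
        eta=keep_eta, sigma2=keep_s2, alpha=keep_alpha, strata_counts=counts,
        acceptance=rates, config=config, step_sizes=dict(step_sizes),
        warnings_=warns,
    )


def rw_metropolis(
    logpost, x0: np.ndarray, step: float, n_draws: int, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Plain Gaussian random-walk Metropolis kernel (the same accept rule
    the P-step uses), exposed for targeted correctness checks."""
    x = np.atleast_1d(np.asarray(x0, dtype=float))
    out = np.empty((n_draws, len(x)))
    cur = logpost(x)
    acc = 0
    for i in range(n_draws):
        prop = x + step * rng.standard_normal(len(x))
        cand = logpost(prop)
        if np.isfinite(cand) and np.log(rng.random()) < cand - cur:
            x, cur = prop, cand
            acc += 1
        out[i] = x
    return out, acc / n_draws


def diagnostics(draws: PosteriorDraws) -> dict:
    """Effective sample sizes, acceptance rates and trace summaries."""
    import arviz as az

    report = {"acceptance": draws.acceptance, "ess": {}, "flags": list(draws.warnings_)}

    def add(name, chain):
        if np.ptp(chain) == 0:
            report["ess"][name] = float("nan")
            report["flags"].append(f"chain {name} is constant (degenerate ESS)")
            return
        report["ess"][name] = float(az.ess(chain[None, :]))

    for g in draws.eta:
        lab = st.STRATUM_LABELS[g]
        for j in range(draws.eta[g].shape[1]):
            add(f"eta_{lab}[{j}]", draws.eta[g][:, j])
        add(f"sigma2_{lab}", draws.sigma2[g])
    for g in draws.alpha:
        lab = st.STRATUM_LABELS[g]
        for j in range(draws.alpha[g].shape[1]):
            add(f"alpha_{lab}[{j}]", draws.alpha[g][:, j])
    return report


def split_rhat(chains: list[np.ndarray]) -> float:
    """Potential scale reduction across independently seeded runs."""
    import arviz as az

    m = min(len(c) for c in chains)
    stacked = np.stack([c[:m] for c in chains])
    return float(az.rhat(stacked))
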