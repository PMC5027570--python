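"""Registry-like synthetic cohorts with known principal strata.

The generator emulates the *structure* of an ALS clinic registry —
baseline covariates, a visit stream, a confounded time to gastrostomy
(PEG) treatment, death competing with outcome measurement — with every
latent quantity known: stratum labels, stratum probabilities, and the
true always-survivor treatment effect.  A single "frailty" index (a
linear combination of the standardized covariates) drives treatment
uptake, stratum membership and the outcome level, so treatment is
confounded and survivor pools differ by arm; a proportional-hazards
Weibull treatment-time model makes the Cox GPS correctly specified at
the default shape.

Everything is emitted both as derived analysis rows and as a raw
visit-level registry table, so cohort ingestion can be exercised
end-to-end and checked to reproduce (Z, S, Y) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cohort as ch
from . import effects as ef
from . import propensity as ps
from . import sampler as sp
from .strata import DL, LD, LL, STRATUM_LABELS, stratum_survival

CONTINUOUS_COVARIATES = ["age_dx", "bmi0", "fvc0", "dtdx_days"]
BINARY_COVARIATES = ["female", "spinal_onset"]
ALL_COVARIATES = CONTINUOUS_COVARIATES + BINARY_COVARIATES


@dataclass
class SyntheticTruth:
    """Generator parameters, including the true SACE.

    Covariate scales mimic an ALS clinic population (ages in the 60s,
    baseline BMI around 25, percent-predicted FVC around 70).  The
    frailty index loads on low FVC, high age and bulbar (non-spinal)
    onset; ``confounding`` scales how strongly it pushes treatment
    uptake, and ``frailty_to_death`` how strongly it pushes subjects
    from the always-survivor stratum toward the DD stratum.
    """

    horizon_days: int = 365
    # covariate distribution
    age_mean: float = 63.0
    age_sd: float = 11.5
    bmi_mean: float = 25.3
    bmi_sd: float = 5.7
    fvc_mean: float = 71.0
    fvc_sd: float = 26.0
    dtdx_mean: float = 180.0
    dtdx_sd: float = 120.0
    p_female: float = 0.45
    p_spinal: float = 0.67
    # treatment-time model: Weibull PH on the frailty index
    weibull_shape: float = 1.3
    treatment_log_rate: float = -8.6   # log h0; tuned for ~1/3 treated by 1 yr
    confounding: float = 0.8           # frailty coefficient in the hazard
    # strata model: multinomial logit on [1, frailty], reference DD
    strata_intercepts: dict[str, float] = field(
        default_factory=lambda: {"LL": 0.10, "LD": -2.1, "DL": -2.6}
    )
    frailty_to_death: float = 0.9      # subtracted from live-stratum logits
    # outcome model (BMI at one year)
    outcome_intercepts: dict[str, float] = field(
        default_factory=lambda: {"LL": 25.0, "LD": 22.5, "DL": 24.0}
    )
    frailty_to_outcome: float = -1.5
    eta_z: float = 2.5                 # true SACE at delta = 0
    eta_t: float = -0.35               # true slope in months from treatment
    sigma2: dict[str, float] = field(
        default_factory=lambda: {"LL": 4.0, "LD": 4.0, "DL": 4.0}
    )

    def null_effect(self) -> "SyntheticTruth":
        return replace(self, eta_z=0.0, eta_t=0.0)

    def unconfounded(self) -> "SyntheticTruth":
        return replace(self, confounding=0.0, frailty_to_death=0.0,
                       frailty_to_outcome=0.0)


def _frailty(cov: pd.DataFrame, truth: SyntheticTruth) -> np.ndarray:
    """Standardized disease-severity index; higher = sicker."""
    z_age = (cov["age_dx"] - truth.age_mean) / truth.age_sd
    z_fvc = (cov["fvc0"] - truth.fvc_mean) / truth.fvc_sd
    raw = 0.6 * z_age - 0.8 * z_fvc - 0.5 * (cov["spinal_onset"] - truth.p_spinal) \
        + 0.3 * (cov["female"] - truth.p_female)
    return (raw / 1.1).to_numpy()


def draw_covariates(truth: SyntheticTruth, n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age_dx": rng.normal(truth.age_mean, truth.age_sd, n),
            "bmi0": rng.normal(truth.bmi_mean, truth.bmi_sd, n),
            "fvc0": np.clip(rng.normal(truth.fvc_mean, truth.fvc_sd, n), 10, 150),
            "dtdx_days": np.clip(rng.normal(truth.dtdx_mean, truth.dtdx_sd, n), 1, 1500),
            "female": (rng.random(n) < truth.p_female).astype(float),
            "spinal_onset": (rng.random(n) < truth.p_spinal).astype(float),
        }
    )


def true_strata_probs(truth: SyntheticTruth, frailty: np.ndarray,
                      monotonicity: bool = False) -> np.ndarray:
    """Closed-form stratum probabilities implied by the generator, as a
    (n, 4) matrix over (LL, LD, DL, DD)."""
    n = len(frailty)
    logits = np.zeros((n, 4))
    logits[:, LL] = truth.strata_intercepts["LL"] - truth.frailty_to_death * frailty
    logits[:, LD] = truth.strata_intercepts["LD"] - 0.4 * truth.frailty_to_death * frailty
    logits[:, DL] = (
        -np.inf if monotonicity else truth.strata_intercepts["DL"]
        - 0.4 * truth.frailty_to_death * frailty
    )
    with np.errstate(over="ignore"):
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def generate_cohort(
    truth: SyntheticTruth,
    n: int,
    seed: int,
    monotonicity: bool = False,
) -> dict:
    """Draw a full synthetic cohort.

    Returns a dict with the derived analysis frame (``rows``), the
    latent stratum labels (``latent_strata``), the frailty index, and a
    visit-level ``registry`` frame suitable for ``cohort.load_registry``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cov = draw_covariates(truth, n, rng)
    frailty = _frailty(cov, truth)

    # latent time to treatment: Weibull PH, T = (E / (h0 e^lp))^(1/k)
    lp = truth.confounding * frailty
    scale = np.exp(truth.treatment_log_rate + lp)
    T = (rng.exponential(1.0, n) / scale) ** (1.0 / truth.weibull_shape)
    treatment_day = np.where(T <= truth.horizon_days, np.maximum(np.round(T), 1), np.nan)
    Z = (~np.isnan(treatment_day)).astype(int)

    # latent stratum, then survival implied by (G, Z)
    pi = true_strata_probs(truth, frailty, monotonicity)
    if (pi.max(axis=1) >= 0.999).all():
        import warnings

        warnings.warn("degenerate truth: one stratum dominates everywhere")
    u = rng.random(n)
    G = (pi.cumsum(axis=1) < u[:, None]).sum(axis=1)
    S = np.array([stratum_survival(g, z) for g, z in zip(G, Z)])

    t_months = np.where(
        Z == 1, (truth.horizon_days - treatment_day) / ch.DAYS_PER_MONTH, 0.0
    )
    mean = np.full(n, np.nan)
    for g, lab in ((LL, "LL"), (LD, "LD"), (DL, "DL")):
        m = G == g
        mean[m] = (
            truth.outcome_intercepts[lab]
            + truth.frailty_to_outcome * frailty[m]
        )
    mean[G == LL] += truth.eta_z * Z[G == LL] + truth.eta_t * (
        Z[G == LL] * t_months[G == LL]
    )
    sd = np.ones(n)
    for g, lab in ((LL, "LL"), (LD, "LD"), (DL, "DL")):
        sd[G == g] = np.sqrt(truth.sigma2[lab])
    Y = np.where(S == 1, mean + sd * rng.standard_normal(n), np.nan)

    death_day = np.full(n, np.nan)
    dead = S == 0
    lo = np.where(Z == 1, np.nan_to_num(treatment_day, nan=0.0) + 1.0, 30.0)
    lo = np.minimum(lo, truth.horizon_days - 2)
    death_day[dead] = np.floor(
        lo[dead] + rng.random(dead.sum()) * (truth.horizon_days - lo[dead])
    )

    rows = pd.DataFrame(
        {
            "subject_id": [f"s{i:05d}" for i in range(n)],
            "Z": Z,
            "S": S,
            "Y": Y,
            "time_from_treatment_months": t_months,
            "treatment_day": treatment_day,
            "death_day": death_day,
            **{c: cov[c] for c in ALL_COVARIATES},
        }
    )
    registry = _emit_registry(rows, truth, rng)
    return {
        "rows": rows,
        "latent_strata": G,
        "frailty": frailty,
        "registry": registry,
        "truth": truth,
    }


def _emit_registry(rows: pd.DataFrame, truth: SyntheticTruth,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Visit-level table that round-trips through cohort ingestion to
    the exact (Z, S, Y) of ``rows``.

    Survivors get 3-8 visits with the last in-horizon outcome visit
    carrying Y; subjects who die get follow-up visits strictly before
    death with outcome values that are never used (Y undefined)."""
    out = []
    horizon = truth.horizon_days
    for r in rows.itertuples(index=False):
        if r.S == 1:
            n_visits = int(rng.integers(3, 9))
            days = np.sort(
                rng.choice(np.arange(30, horizon), size=n_visits - 1, replace=False)
            )
            visit_days = [0, *days.tolist()]
            bmi = np.linspace(r.bmi0, r.Y, len(visit_days))
            bmi[-1] = r.Y  # the latest in-horizon outcome visit defines Y
        else:
            last = int(r.death_day) - 1
            visit_days = [0]
            if last >= 15:
                k = int(rng.integers(1, min(4, max(2, last // 60) + 1)))
                extra = np.unique(rng.integers(10, last + 1, size=k))
                visit_days += extra.tolist()
            else:
                visit_days += [max(1, last)]
            bmi = np.linspace(r.bmi0, r.bmi0 - 1.0, len(visit_days))
        fvc = np.linspace(r.fvc0, max(r.fvc0 - 12.0, 5.0), len(visit_days))
        for j, d in enumerate(visit_days):
            out.append(
                {
                    "subject_id": r.subject_id,
                    "day": int(d),
                    "outcome": bmi[j],
                    "fvc": fvc[j],
                    "treatment_day": r.treatment_day,
                    "death_day": r.death_day,
                    "age_dx": r.age_dx,
                    "bmi0": r.bmi0,
                    "fvc0": r.fvc0,
                    "dtdx_days": r.dtdx_days,
                    "female": r.female,
                    "spinal_onset": r.spinal_onset,
                }
            )
    return pd.DataFrame(out)


def fit_replicate(
    rows: pd.DataFrame,
    model_type: str = "time",
    ps_order: int = 1,
    monotonicity: bool = False,
    n_iter: int = 2_000,
    burn_in: int = 500,
    seed: int = 0,
    horizon_days: int = 365,
) -> ef.SaceSummary:
    """One full pipeline pass: propensity fit, term expansion, DA-MCMC,
    SACE summary."""
    X = rows[ALL_COVARIATES].to_numpy(dtype=float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    if model_type == "time":
        time, event = ps.gps_times(rows, horizon_days)
        model = ps.CoxGPS(horizon_days).fit(Xs, time, event,
                                            feature_names=ALL_COVARIATES)
    else:
        model = ps.LogisticPropensityScore().fit(
            Xs, rows["Z"].to_numpy(), feature_names=ALL_COVARIATES
        )
    terms = ps.expand_ps_terms(model.scores_, ps_order) if ps_order else None
    data = sp.prepare_model_data(rows, model_type, terms, monotonicity)
    cfg = sp.SamplerConfig(
        n_iter=n_iter, burn_in=burn_in, seed=seed,
        model_type=model_type, monotonicity=monotonicity, ps_order=ps_order,
    )
    draws = sp.run_da_mcmc(data, config=cfg)
    return ef.compute_sace(draws)


@dataclass
class RecoveryResult:
    estimates: pd.DataFrame     # per replicate x term
    bias: dict[str, float]
    rmse: dict[str, float]
    coverage: dict[str, float]
    n_failed: int


def recovery_experiment(
    truth: SyntheticTruth,
    n: int = 600,
    replicates: int = 50,
    seed: int = 0,
    model_type: str = "time",
    ps_order: int = 1,
    monotonicity: bool = False,
    n_iter: int = 2_000,
    burn_in: int = 500,
    include_naive: bool = False,
) -> RecoveryResult:
    """Repeated generate-and-fit runs; aggregates bias, RMSE and
    empirical 95%-interval coverage of the treatment terms against the
    generator's truth."""
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    true_vals = {"Z": truth.eta_z}
    if model_type == "time":
        true_vals["time_from_treatment_months"] = truth.eta_t
    recs, n_failed = [], 0
    for r in range(replicates):
        try:
            sim = generate_cohort(truth, n, seed=seed + r, monotonicity=monotonicity)
            summ = fit_replicate(
                sim["rows"], model_type, ps_order, monotonicity,
                n_iter, burn_in, seed=seed + r,
            )
            for term, t in summ.terms.items():
                recs.append({"replicate": r, "term": term, **t})
            if include_naive:
                X = sim["rows"][ALL_COVARIATES].to_numpy(dtype=float)
                naive = ef.naive_analysis(sim["rows"], model_type, None)
                for _, row in naive.iterrows():
                    if row["term"] in true_vals:
                        recs.append(
                            {
                                "replicate": r,
                                "term": f"naive_{row['term']}",
                                "mean": row["estimate"],
                                "lower": row["lower"],
                                "upper": row["upper"],
                                "significant": not row["lower"] <= 0 <= row["upper"],
                            }
                        )
        except Exception:
            n_failed += 1
    if n_failed > 0.2 * replicates:
        raise RuntimeError(f"{n_failed}/{replicates} replicates failed")
    est = pd.DataFrame(recs)
    bias, rmse, coverage = {}, {}, {}
    for term, tv in true_vals.items():
        for prefix in ([""] if not include_naive else ["", "naive_"]):
            sub = est[est["term"] == prefix + term]
            if not len(sub):
                continue
            err = sub["mean"].to_numpy() - tv
            bias[prefix + term] = float(err.mean())
            rmse[prefix + term] = float(np.sqrt((err**2).mean()))
            coverage[prefix + term] = float(
                ((sub["lower"] <= tv) & (tv <= sub["upper"])).mean()
            )
    return RecoveryResult(
        estimates=est, bias=bias, rmse=rmse, coverage=coverage, n_failed=n_failed
    )


def strata_oracle_check(
    sim: dict, monotonicity: bool = False, threshold: float = 0.9
) -> dict:
    """Calibration of conditional membership probabilities at the true
    generator parameters against the latent labels."""
    from . import strata as st_mod
    from .outcome import normal_logdensity

    truth: SyntheticTruth = sim["truth"]
    rows, G = sim["rows"], sim["latent_strata"]
    pi = true_strata_probs(truth, sim["frailty"], monotonicity)
    n = len(rows)
    rho = np.zeros((n, 4))
    Z = rows["Z"].to_numpy(dtype=int)
    S = rows["S"].to_numpy(dtype=int)
    Y = rows["Y"].to_numpy(dtype=float)
    tm = rows["time_from_treatment_months"].to_numpy(dtype=float)
    for i in range(n):
        log_pi_active = np.log(
            np.maximum(pi[i][list(st_mod.active_strata(monotonicity))], 1e-300)
        )
        log_f = None
        if S[i] == 1:
            log_f = {}
            for g, lab in ((LL, "LL"), (LD, "LD"), (DL, "DL")):
                mu = truth.outcome_intercepts[lab] + truth.frailty_to_outcome * sim[
                    "frailty"
                ][i]
                if g == LL:
                    mu += truth.eta_z * Z[i] + truth.eta_t * Z[i] * tm[i]
                log_f[g] = float(
                    normal_logdensity(Y[i], mu, truth.sigma2[lab])
                )
        rho[i] = st_mod.membership_probs(
            Z[i], S[i], log_pi_active, log_f, monotonicity
        )
    conf = rho.max(axis=1) > threshold
    match = rho.argmax(axis=1)[conf] == G[conf]
    bins = np.linspace(0, 1, 11)
    calib = []
    for g in range(4):
        sel = rho[:, g] > 0
        if sel.sum() < 10:
            continue
        digit = np.clip(np.digitize(rho[sel, g], bins) - 1, 0, 9)
        for b in np.unique(digit):
            m = digit == b
            calib.append(
                {
                    "stratum": STRATUM_LABELS[g],
                    "rho_mid": float(bins[b] + 0.05),
                    "empirical": float((G[sel][m] == g).mean()),
                    "n": int(m.sum()),
                }
            )
    return {
        "n_confident": int(conf.sum()),
        "confident_match_rate": float(match.mean()) if conf.any() else np.nan,
        "calibration": pd.DataFrame(calib),
        "rho": rho,
    }
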