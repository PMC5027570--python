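"""Posterior summaries: SACE, the effect-versus-time curve, the naive
survivors-only comparator, and the model-variant comparison grid.

The SACE is the treated-vs-untreated mean outcome contrast inside the
always-survivor stratum.  In the binary treatment model it is the LL
treatment coefficient; in the time-of-treatment model the contrast at a
lag of ``delta`` months from treatment to the horizon is
``eta_Z + eta_T * delta``, summarized pointwise over the posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .sampler import PosteriorDraws


@dataclass
class SaceSummary:
    model_type: str
    monotonicity: bool
    ps_order: int
    terms: dict[str, dict]  # name -> {mean, lower, upper, significant}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, t in self.terms.items():
            rows.append(
                {
                    "model_type": self.model_type,
                    "monotonicity": self.monotonicity,
                    "ps_order": self.ps_order,
                    "term": name,
                    **t,
                }
            )
        return pd.DataFrame(rows)


def _summarize(chain: np.ndarray, level: float = 0.95) -> dict:
    if len(chain) == 0:
        raise ValueError("empty posterior chain")
    lo, hi = np.quantile(chain, [(1 - level) / 2, 1 - (1 - level) / 2])
    return {
        "mean": float(chain.mean()),
        "lower": float(lo),
        "upper": float(hi),
        "significant": bool(lo > 0 or hi < 0),
    }


def compute_sace(draws: PosteriorDraws, level: float = 0.95) -> SaceSummary:
    """Posterior mean and equal-tailed credible interval of the LL
    treatment coefficients.  A term is flagged significant exactly when
    its interval excludes 0."""
    chains = draws.treatment_chains()
    terms = {name: _summarize(c, level) for name, c in chains.items()}
    cfg = draws.config
    return SaceSummary(
        model_type=cfg.model_type,
        monotonicity=cfg.monotonicity,
        ps_order=cfg.ps_order,
        terms=terms,
    )


@dataclass
class EffectCurve:
    delta_months: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta_months": self.delta_months,
                "mean": self.mean,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def effect_curve(
    draws: PosteriorDraws,
    delta_grid: np.ndarray | None = None,
    level: float = 0.95,
) -> EffectCurve:
    """Treatment effect eta_Z + eta_T * delta over a grid of months from
    treatment to the horizon (time model only)."""
    if draws.config.model_type != "time":
        raise ValueError("effect curve requires time-of-treatment model draws")
    if delta_grid is None:
        delta_grid = np.arange(0.0, 12.0 + 1e-9, 0.25)
    delta_grid = np.asarray(delta_grid, dtype=float)
    chains = draws.treatment_chains()
    vals = chains["Z"][:, None] + np.outer(
        chains["time_from_treatment_months"], delta_grid
    )
    q = np.quantile(vals, [(1 - level) / 2, 1 - (1 - level) / 2], axis=0)
    return EffectCurve(
        delta_months=delta_grid,
        mean=vals.mean(axis=0),
        lower=q[0],
        upper=q[1],
    )


def naive_analysis(
    df: pd.DataFrame,
    model_type: str = "binary",
    ps_terms: np.ndarray | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Survivors-only ordinary least squares, ignoring principal strata.

    Fits Y on the same design the LL stratum uses (intercept, treatment
    term(s), optional propensity columns) among subjects alive at the
    horizon, with normal-theory confidence intervals.  This estimator is
    subject to survivor-selection bias whenever survival depends on
    stratum: the treated and untreated survivor pools mix different
    strata.
    """
    surv = df["S"].to_numpy() == 1
    if not surv.any():
        raise ValueError("no survivors; naive analysis undefined")
    y = df.loc[surv, "Y"].to_numpy(dtype=float)
    Z = df.loc[surv, "Z"].to_numpy(dtype=float)
    names = ["intercept", "Z"]
    cols = [np.ones(surv.sum()), Z]
    if model_type == "time":
        tm = df.loc[surv, "time_from_treatment_months"].to_numpy(dtype=float)
        cols.append(Z * tm)
        names.append("time_from_treatment_months")
    if ps_terms is not None and np.size(ps_terms):
        P = np.atleast_2d(np.asarray(ps_terms, dtype=float).T).T[surv]
        cols.append(P)
        names += [f"ps^{k}" for k in range(1, P.shape[1] + 1)]
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular naive design; columns {names}")
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=1 - level)
    return pd.DataFrame(
        {
            "term": names,
            "estimate": res.params,
            "lower": ci[:, 0],
            "upper": ci[:, 1],
            "n": int(surv.sum()),
        }
    )


def results_report(summaries: list[SaceSummary]) -> pd.DataFrame:
    """Stack fitted model variants (treatment model x propensity order x
    monotonicity) into one comparison table; absent variants are simply
    absent rows."""
    if not summaries:
        return pd.DataFrame(
            columns=["model_type", "monotonicity", "ps_order", "term",
                     "mean", "lower", "upper", "significant"]
        )
    frames = [s.to_frame() for s in summaries]
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["model_type", "ps_order", "monotonicity", "term"]
    ).reset_index(drop=True)
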