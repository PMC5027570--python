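"""Cohort construction from a longitudinal clinic registry.

Turns a visit-level registry table into one analysis row per subject:
a binary treatment indicator ``Z`` (treated within the follow-up horizon),
a survival indicator ``S`` (alive at the horizon), the outcome ``Y``
measured at the latest eligible visit, and the months elapsed from
treatment to the horizon.  Outcomes of subjects who die before the
horizon are censored by death: ``Y`` is undefined, not merely missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DAYS_PER_MONTH = 30.4375

#: default follow-up horizon t^o (days from the baseline visit)
DEFAULT_HORIZON_DAYS = 365
#: default survival cap: subjects surviving past this are excluded
DEFAULT_MAX_SURVIVAL_DAYS = 1826


@dataclass
class SubjectRecord:
    """Raw registry entity: baseline covariates plus the visit stream.

    ``visits`` is an ordered list of ``(day, outcome, fvc)`` tuples with
    ``day`` counted from the first (baseline) visit; ``outcome``/``fvc``
    may be None when not measured at that visit.
    """

    subject_id: str
    baseline_covariates: dict[str, float]
    visits: list[tuple[int, float | None, float | None]]
    treatment_day: int | None = None
    death_day: int | None = None

    def __post_init__(self) -> None:
        self.visits = sorted(self.visits, key=lambda v: v[0])
        if self.visits and self.visits[0][0] != 0:
            # re-anchor offsets so the first visit is the baseline t_0
            base = self.visits[0][0]
            self.visits = [(d - base, y, f) for d, y, f in self.visits]
            if self.treatment_day is not None:
                self.treatment_day -= base
            if self.death_day is not None:
                self.death_day -= base

    @property
    def last_visit_day(self) -> int:
        return self.visits[-1][0] if self.visits else 0


@dataclass
class ExclusionReport:
    """Per-rule exclusion accounting; a subject counts only under the
    first rule it violates, so counts always conserve."""

    n_input: int
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def n_remaining(self) -> int:
        return self.n_input - sum(self.excluded.values())

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "excluded": dict(self.excluded),
            "n_remaining": self.n_remaining,
        }


RULE_NO_FOLLOWUP = "no_followup_within_horizon"
RULE_LONG_SURVIVAL = "survival_exceeds_maximum"
RULE_NO_OUTCOME = "no_postbaseline_outcome"


def load_registry(path: str, schema: dict[str, str] | None = None) -> list[SubjectRecord]:
    """Read a delimited visit-level registry file into SubjectRecords.

    One row per clinic visit.  ``schema`` maps logical names
    (``subject_id``, ``day``, ``outcome``, ``fvc``, ``treatment_day``,
    ``death_day``, plus any baseline-covariate names) to column names;
    identity mapping by default.  Day offsets are recomputed relative to
    each subject's first visit.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    schema = schema or {}

    def col(logical: str) -> str:
        return schema.get(logical, logical)

    mandatory = [col("subject_id"), col("day")]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"registry file is missing mandatory column(s): {missing}")

    reserved = {"subject_id", "day", "outcome", "fvc", "treatment_day", "death_day"}
    covariate_cols = {
        logical: actual for logical, actual in schema.items() if logical not in reserved
    }
    if not covariate_cols:
        per_subject = {col(c) for c in reserved if col(c) in df.columns}
        covariate_cols = {
            c: c for c in df.columns if c not in per_subject
        }

    records = []
    for sid, grp in df.groupby(col("subject_id"), sort=True):
        days = grp[col("day")].to_numpy()
        if len(np.unique(days)) != len(days):
            raise ValueError(f"duplicate (subject, day) visit rows for subject {sid!r}")
        grp = grp.sort_values(col("day"))

        def scalar(logical: str) -> float | None:
            c = col(logical)
            if c not in grp.columns:
                return None
            v = grp[c].iloc[0]
            return None if pd.isna(v) else float(v)

        def opt(row, logical: str) -> float | None:
            c = col(logical)
            if c not in grp.columns:
                return None
            v = row[c]
            return None if pd.isna(v) else float(v)

        visits = [
            (int(row[col("day")]), opt(row, "outcome"), opt(row, "fvc"))
            for _, row in grp.iterrows()
        ]
        baseline = {}
        for logical, actual in covariate_cols.items():
            v = grp[actual].iloc[0]
            baseline[logical] = float(v) if not pd.isna(v) else np.nan
        t = scalar("treatment_day")
        d = scalar("death_day")
        records.append(
            SubjectRecord(
                subject_id=str(sid),
                baseline_covariates=baseline,
                visits=visits,
                treatment_day=None if t is None else int(t),
                death_day=None if d is None else int(d),
            )
        )
    return records


def _alive_at(record: SubjectRecord, day: int) -> bool:
    return record.death_day is None or record.death_day > day


def _has_postbaseline_outcome(record: SubjectRecord, horizon_days: int) -> bool:
    return any(
        0 < d <= horizon_days and y is not None for d, y, _ in record.visits
    )


def apply_exclusions(
    records: list[SubjectRecord],
    horizon_days: int = DEFAULT_HORIZON_DAYS,
    max_survival_days: int = DEFAULT_MAX_SURVIVAL_DAYS,
) -> tuple[list[SubjectRecord], ExclusionReport]:
    """Apply the cohort exclusion rules in order, first-rule-wins.

    1. no follow-up visit within ``horizon_days`` of baseline;
    2. survival beyond ``max_survival_days`` post-baseline (death after
       the cap, or no death recorded and observed alive past the cap);
    3. alive at the horizon but no post-baseline outcome measurement
       within the horizon.
    """
    report = ExclusionReport(
        n_input=len(records),
        excluded={RULE_NO_FOLLOWUP: 0, RULE_LONG_SURVIVAL: 0, RULE_NO_OUTCOME: 0},
    )
    kept = []
    for rec in records:
        if not any(0 < d <= horizon_days for d, _, _ in rec.visits):
            report.excluded[RULE_NO_FOLLOWUP] += 1
        elif (rec.death_day is not None and rec.death_day > max_survival_days) or (
            rec.death_day is None and rec.last_visit_day > max_survival_days
        ):
            report.excluded[RULE_LONG_SURVIVAL] += 1
        elif _alive_at(rec, horizon_days) and not _has_postbaseline_outcome(
            rec, horizon_days
        ):
            report.excluded[RULE_NO_OUTCOME] += 1
        else:
            kept.append(rec)
    return kept, report


def derive_analysis_row(
    record: SubjectRecord, horizon_days: int = DEFAULT_HORIZON_DAYS
) -> dict:
    """Derive the per-subject analysis variables at the horizon t^o.

    Z = treated on or before the horizon; S = alive at the horizon;
    Y = outcome at the latest visit <= horizon with a non-missing
    outcome (undefined when S=0); ``time_from_treatment_months`` =
    (horizon - treatment day)/30.4375 for treated subjects, else 0.
    """
    z = int(
        record.treatment_day is not None and record.treatment_day <= horizon_days
    )
    s = int(_alive_at(record, horizon_days))
    y = np.nan
    if s == 1:
        eligible = [
            (d, v) for d, v, _ in record.visits if d <= horizon_days and v is not None
        ]
        if not eligible:
            raise ValueError(
                f"subject {record.subject_id}: alive at horizon with no eligible "
                "outcome visit (should have been excluded)"
            )
        y = eligible[-1][1]
    t_months = (
        (horizon_days - record.treatment_day) / DAYS_PER_MONTH if z == 1 else 0.0
    )
    row = {
        "subject_id": record.subject_id,
        "Z": z,
        "S": s,
        "Y": y,
        "time_from_treatment_months": t_months,
        "treatment_day": record.treatment_day if z == 1 else np.nan,
    }
    row.update(record.baseline_covariates)
    return row


def derive_cohort(
    records: list[SubjectRecord], horizon_days: int = DEFAULT_HORIZON_DAYS
) -> pd.DataFrame:
    """Vector version of :func:`derive_analysis_row`; one row per subject."""
    return pd.DataFrame([derive_analysis_row(r, horizon_days) for r in records])


def normalize_covariates(
    df: pd.DataFrame, which: list[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Standardize the listed continuous covariates to mean 0, sd 1.

    Returns the transformed frame and the (mean, sd) pairs used, for
    reporting and for applying the same scaling to new data.
    """
    out = df.copy()
    scales = {}
    for name in which:
        x = out[name].to_numpy(dtype=float)
        mu = float(np.nanmean(x))
        sd = float(np.nanstd(x, ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"covariate {name!r} has zero spread; cannot standardize")
        out[name] = (x - mu) / sd
        scales[name] = (mu, sd)
    return out, scales


def cohort_summary(
    df: pd.DataFrame,
    continuous: list[str] | None = None,
    binary: list[str] | None = None,
) -> pd.DataFrame:
    """Per-arm descriptive comparison of treated vs untreated subjects.

    Continuous variables: mean/sd per arm and a Welch two-sample t-test;
    binary variables (and the survival proportion) : proportion and count
    per arm and a chi-square test on the 2x2 table.
    """
    treated = df[df["Z"] == 1]
    untreated = df[df["Z"] == 0]
    small = len(treated) < 2 or len(untreated) < 2
    rows = []

    def welch_p(a, b):
        if small:
            return np.nan
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if np.nanstd(a) == 0 and np.nanstd(b) == 0 and np.nanmean(a) == np.nanmean(b):
            return 1.0
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)

    def chisq_p(x1, x0):
        if small:
            return np.nan
        table = np.array(
            [
                [x1.sum(), len(x1) - x1.sum()],
                [x0.sum(), len(x0) - x0.sum()],
            ]
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            return 1.0
        if table[0, 0] / len(x1) == table[1, 0] / len(x0):
            return 1.0
        return float(stats.chi2_contingency(table, correction=False).pvalue)

    for name in continuous or []:
        a = treated[name].to_numpy(dtype=float)
        b = untreated[name].to_numpy(dtype=float)
        rows.append(
            {
                "variable": name,
                "kind": "continuous",
                "treated_mean": np.nanmean(a) if len(a) else np.nan,
                "treated_sd": np.nanstd(a, ddof=1) if len(a) > 1 else np.nan,
                "untreated_mean": np.nanmean(b) if len(b) else np.nan,
                "untreated_sd": np.nanstd(b, ddof=1) if len(b) > 1 else np.nan,
                "p_value": welch_p(a, b),
            }
        )
    binaries = list(binary or []) + ["S"]
    for name in binaries:
        a = treated[name].to_numpy(dtype=float)
        b = untreated[name].to_numpy(dtype=float)
        rows.append(
            {
                "variable": "proportion_surviving" if name == "S" else name,
                "kind": "binary",
                "treated_mean": a.mean() if len(a) else np.nan,
                "treated_sd": a.sum() if len(a) else np.nan,
                "untreated_mean": b.mean() if len(b) else np.nan,
                "untreated_sd": b.sum() if len(b) else np.nan,
                "p_value": chisq_p(a, b),
            }
        )
    return pd.DataFrame(rows)
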