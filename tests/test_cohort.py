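"""Cohort ingestion, exclusion accounting, and variable derivation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sacekit import cohort as ch
from sacekit import synthetic as syn


def write_registry(tmp_path, rows, name="reg.csv"):
    p = tmp_path / name
    pd.DataFrame(rows).to_csv(p, index=False)
    return str(p)


class TestLoadRegistry:
    def test_single_subject_three_visits(self, tmp_path):
        p = write_registry(
            tmp_path,
            [
                {"subject_id": "a", "day": 0, "outcome": 25.0, "bmi0": 25.0},
                {"subject_id": "a", "day": 100, "outcome": 24.0, "bmi0": 25.0},
                {"subject_id": "a", "day": 200, "outcome": 23.5, "bmi0": 25.0},
            ],
        )
        recs = ch.load_registry(p)
        assert len(recs) == 1
        assert [v[0] for v in recs[0].visits] == [0, 100, 200]
        assert recs[0].baseline_covariates["bmi0"] == 25.0

    def test_out_of_order_visits_are_sorted(self, tmp_path):
        p = write_registry(
            tmp_path,
            [
                {"subject_id": "a", "day": 200, "outcome": 23.5},
                {"subject_id": "a", "day": 0, "outcome": 25.0},
                {"subject_id": "a", "day": 100, "outcome": 24.0},
            ],
        )
        recs = ch.load_registry(p)
        assert [v[0] for v in recs[0].visits] == [0, 100, 200]

    def test_duplicate_visit_day_raises(self, tmp_path):
        p = write_registry(
            tmp_path,
            [
                {"subject_id": "a", "day": 0, "outcome": 25.0},
                {"subject_id": "a", "day": 0, "outcome": 24.0},
            ],
        )
        with pytest.raises(ValueError, match="duplicate.*'a'"):
            ch.load_registry(p)

    def test_missing_mandatory_column_raises(self, tmp_path):
        p = write_registry(tmp_path, [{"subject_id": "a", "outcome": 25.0}])
        with pytest.raises(ValueError, match="mandatory"):
            ch.load_registry(p)

    def test_synthetic_registry_round_trip(self, tmp_path):
        """Writing the generator's visit file and re-deriving the cohort
        reproduces (Z, S, Y, months-from-treatment) exactly."""
        sim = syn.generate_cohort(syn.SyntheticTruth(), n=500, seed=21)
        p = tmp_path / "registry.csv"
        sim["registry"].to_csv(p, index=False)
        recs = ch.load_registry(str(p))
        kept, report = ch.apply_exclusions(recs)
        assert report.n_remaining == 500
        derived = ch.derive_cohort(kept).set_index("subject_id")
        orig = sim["rows"].set_index("subject_id")
        assert (derived["Z"] == orig["Z"]).all()
        assert (derived["S"] == orig["S"]).all()
        assert np.allclose(derived["Y"].fillna(-1), orig["Y"].fillna(-1))
        assert np.allclose(
            derived["time_from_treatment_months"],
            orig["time_from_treatment_months"],
        )


def rec(sid="s", visits=(), treatment_day=None, death_day=None, **cov):
    return ch.SubjectRecord(
        subject_id=sid,
        baseline_covariates=cov,
        visits=list(visits),
        treatment_day=treatment_day,
        death_day=death_day,
    )


class TestExclusions:
    def test_baseline_only_subject_excluded_under_rule_one(self):
        kept, rep = ch.apply_exclusions([rec(visits=[(0, 25.0, 70.0)])])
        assert kept == []
        assert rep.excluded[ch.RULE_NO_FOLLOWUP] == 1

    def test_first_rule_wins_for_multi_violators(self):
        # no follow-up within a year AND survival past the cap
        r = rec(visits=[(0, 25.0, None), (2000, 24.0, None)], death_day=2100)
        _, rep = ch.apply_exclusions([r])
        assert rep.excluded[ch.RULE_NO_FOLLOWUP] == 1
        assert rep.excluded[ch.RULE_LONG_SURVIVAL] == 0

    def test_long_survival_and_missing_outcome_rules(self):
        long_surv = rec(
            "b", visits=[(0, 25.0, None), (100, 24.0, None)], death_day=1900
        )
        no_outcome = rec("c", visits=[(0, 25.0, None), (100, None, 70.0)])
        kept, rep = ch.apply_exclusions([long_surv, no_outcome])
        assert kept == []
        assert rep.excluded[ch.RULE_LONG_SURVIVAL] == 1
        assert rep.excluded[ch.RULE_NO_OUTCOME] == 1

    def test_dead_subject_not_held_to_outcome_rule(self):
        died = rec("d", visits=[(0, 25.0, None), (50, None, 60.0)], death_day=90)
        kept, rep = ch.apply_exclusions([died])
        assert len(kept) == 1 and rep.n_remaining == 1

    def test_empty_input(self):
        kept, rep = ch.apply_exclusions([])
        assert kept == [] and rep.n_input == 0 and rep.n_remaining == 0

    def test_count_conservation_on_random_cohorts(self, rng):
        for _ in range(20):
            recs = []
            for i in range(rng.integers(1, 40)):
                visits = [(0, 25.0, None)]
                if rng.random() < 0.8:
                    out = 24.0 if rng.random() < 0.7 else None
                    visits.append((int(rng.integers(1, 400)), out, None))
                death = int(rng.integers(30, 2500)) if rng.random() < 0.5 else None
                if death is not None:
                    visits = [v for v in visits if v[0] < death]
                    if not visits:
                        visits = [(0, 25.0, None)]
                recs.append(rec(f"s{i}", visits, death_day=death))
            kept, rep = ch.apply_exclusions(recs)
            assert rep.n_input == rep.n_remaining + sum(rep.excluded.values())
            assert rep.n_remaining == len(kept)


class TestDeriveAnalysisRow:
    def test_treated_survivor_arithmetic(self):
        r = rec(
            visits=[(0, 26.0, None), (180, 25.0, None), (330, 24.2, None)],
            treatment_day=100,
        )
        row = ch.derive_analysis_row(r, horizon_days=365)
        assert row["Z"] == 1 and row["S"] == 1
        assert row["Y"] == 24.2  # latest eligible visit
        assert row["time_from_treatment_months"] == pytest.approx(
            (365 - 100) / 30.4375
        )
        assert row["time_from_treatment_months"] == pytest.approx(8.71, abs=0.005)

    def test_death_before_horizon_censors_outcome(self):
        r = rec(visits=[(0, 26.0, None), (150, 25.0, None)], death_day=200)
        row = ch.derive_analysis_row(r)
        assert row["S"] == 0 and np.isnan(row["Y"])

    def test_treatment_after_horizon_is_untreated(self):
        r = rec(visits=[(0, 26.0, None), (300, 25.0, None)], treatment_day=400)
        row = ch.derive_analysis_row(r)
        assert row["Z"] == 0 and row["time_from_treatment_months"] == 0.0

    def test_survivor_without_outcome_visit_flagged(self):
        r = rec(visits=[(0, None, 70.0), (100, None, 65.0)])
        with pytest.raises(ValueError, match="should have been excluded"):
            ch.derive_analysis_row(r)

    def test_outcome_visit_selection_matches_brute_force(self, rng):
        for _ in range(50):
            days = np.sort(rng.choice(np.arange(1, 500), size=6, replace=False))
            vals = [
                float(rng.normal(25, 3)) if rng.random() < 0.7 else None
                for _ in days
            ]
            visits = [(0, 25.0, None)] + [
                (int(d), v, None) for d, v in zip(days, vals)
            ]
            r = rec(visits=visits)
            eligible = [(d, v) for d, v, _ in r.visits if d <= 365 and v is not None]
            row = ch.derive_analysis_row(r)
            assert row["Y"] == max(eligible, key=lambda t: t[0])[1]


class TestNormalizeCovariates:
    def test_standardized_moments(self, als_sim):
        out, scales = ch.normalize_covariates(als_sim["rows"], ["age_dx", "fvc0"])
        for c in ("age_dx", "fvc0"):
            assert abs(out[c].mean()) < 1e-12
            assert abs(out[c].std(ddof=1) - 1) < 1e-12
            assert scales[c][1] > 0

    def test_location_invariance_and_idempotence(self, als_sim):
        df = als_sim["rows"].copy()
        shifted = df.copy()
        shifted["age_dx"] = shifted["age_dx"] + 100.0
        a, _ = ch.normalize_covariates(df, ["age_dx"])
        b, _ = ch.normalize_covariates(shifted, ["age_dx"])
        assert np.allclose(a["age_dx"], b["age_dx"])
        twice, _ = ch.normalize_covariates(a, ["age_dx"])
        assert np.allclose(a["age_dx"], twice["age_dx"])

    def test_zero_spread_raises(self, als_sim):
        df = als_sim["rows"].copy()
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            ch.normalize_covariates(df, ["flat"])


class TestCohortSummary:
    @staticmethod
    def _cohort(n1, surv1, n0, surv0):
        return pd.DataFrame(
            {
                "Z": [1] * n1 + [0] * n0,
                "S": [1] * surv1 + [0] * (n1 - surv1)
                + [1] * surv0 + [0] * (n0 - surv0),
                "Y": np.nan,
            }
        )

    def test_survival_proportion_from_counts(self):
        df = self._cohort(200, 83, 380, 206)
        summ = ch.cohort_summary(df)
        row = summ[summ.variable == "proportion_surviving"].iloc[0]
        assert row["treated_mean"] == pytest.approx(0.415)
        assert row["treated_sd"] == 83  # count column for binary rows

    def test_identical_arms_give_unit_pvalues(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame(
            {
                "Z": [1] * 50 + [0] * 50,
                "S": [1] * 100,
                "Y": np.nan,
                "bmi": np.concatenate([x, x]),
            }
        )
        summ = ch.cohort_summary(df, continuous=["bmi"])
        assert summ[summ.variable == "bmi"].iloc[0]["p_value"] == pytest.approx(1.0)
        surv = summ[summ.variable == "proportion_surviving"].iloc[0]
        assert surv["p_value"] == pytest.approx(1.0)

    def test_chi_square_matches_textbook_formula(self):
        df = self._cohort(60, 25, 80, 50)
        summ = ch.cohort_summary(df)
        p = summ[summ.variable == "proportion_surviving"].iloc[0]["p_value"]
        table = np.array([[25, 35], [50, 30]])
        n = table.sum()
        row, col = table.sum(1), table.sum(0)
        expected = np.outer(row, col) / n
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert p == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-10)

    def test_tiny_arm_reports_unavailable(self):
        df = self._cohort(1, 1, 30, 15)
        summ = ch.cohort_summary(df)
        assert np.isnan(
            summ[summ.variable == "proportion_surviving"].iloc[0]["p_value"]
        )
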