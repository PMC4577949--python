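"""Odds ratios, regression fits, design construction and outcome derivation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from crisnss.corpus import PatientRecord
from crisnss.epi import (
    ContingencyTable2x2,
    DesignSpec,
    EpiError,
    build_design,
    cohort_frame,
    fit_linear,
    fit_logistic,
    fit_ordinal_logistic,
    odds_ratio_2x2,
    outcome_builder,
    reconstruct_counts,
    select_nearest,
)
from crisnss.simulate import CohortParams, generate_cohort


class TestReconstructCounts:
    @pytest.mark.parametrize(
        "n,pct,expected",
        [
            (4592, 45.3, (2080, 2512)),
            (7678, 41.0, (3148, 4530)),  # printed exact count is 3149; +-1 rounding
            (100, 0.0, (0, 100)),
            (7, 14.3, (1, 6)),
        ],
    )
    def test_half_up_rounding(self, n, pct, expected):
        assert reconstruct_counts(n, pct) == expected

    def test_out_of_range_prevalence_rejected(self):
        with pytest.raises(EpiError):
            reconstruct_counts(100, 101.0)


class TestOddsRatio2x2:
    def test_balanced_table_is_unity_with_symmetric_ci(self):
        result = odds_ratio_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert result.odds_ratio == pytest.approx(1.0)
        assert result.ci_low * result.ci_high == pytest.approx(1.0)
        assert result.p_value == pytest.approx(1.0)

    def test_swapping_exposure_rows_gives_reciprocal(self):
        t = ContingencyTable2x2(12, 34, 56, 78)
        r1 = odds_ratio_2x2(t)
        r2 = odds_ratio_2x2(ContingencyTable2x2(56, 78, 12, 34))
        assert r2.odds_ratio == pytest.approx(1.0 / r1.odds_ratio)
        assert r2.ci_low == pytest.approx(1.0 / r1.ci_high)

    def test_zero_cell_errors_without_continuity_flag(self):
        with pytest.raises(EpiError, match="zero cell"):
            odds_ratio_2x2(ContingencyTable2x2(0, 10, 10, 10))
        corrected = odds_ratio_2x2(
            ContingencyTable2x2(0, 10, 10, 10), continuity_correction=True
        )
        assert corrected.odds_ratio == pytest.approx((0.5 * 10.5) / (10.5 * 10.5))

    def test_saturated_logistic_matches_closed_form_to_1e8(self):
        t = ContingencyTable2x2(37, 63, 52, 48)
        closed = odds_ratio_2x2(t)
        exposure = np.r_[np.ones(t.a + t.b), np.zeros(t.c + t.d)]
        y = np.r_[np.ones(t.a), np.zeros(t.b), np.ones(t.c), np.zeros(t.d)]
        X = pd.DataFrame({"const": np.ones_like(exposure), "exposure": exposure})
        fit = fit_logistic(X, y)
        assert fit.term("exposure")["odds_ratio"] == pytest.approx(
            closed.odds_ratio, abs=1e-8
        )
        assert fit.term("exposure")["se"] == pytest.approx(
            np.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d), abs=1e-8
        )


class TestLogistic:
    def test_all_identical_outcome_rejected(self):
        X = pd.DataFrame({"const": np.ones(20), "x": np.arange(20.0)})
        with pytest.raises(EpiError, match="degenerate"):
            fit_logistic(X, np.zeros(20))

    def test_non_binary_outcome_rejected(self):
        X = pd.DataFrame({"const": np.ones(3)})
        with pytest.raises(EpiError, match="binary"):
            fit_logistic(X, np.array([0, 1, 2]))


class TestLinear:
    def test_noise_free_outcome_recovered_exactly(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(
            {"const": 1.0, "exposure": rng.integers(0, 2, 200).astype(float)}
        )
        y = 31.0 + 20.5 * X["exposure"]
        fit = fit_linear(X, y.to_numpy())
        assert fit.term("exposure")["estimate"] == pytest.approx(20.5, abs=1e-10)
        assert fit.term("const")["estimate"] == pytest.approx(31.0, abs=1e-10)

    def test_duplicated_covariate_column_names_aliased_terms(self):
        X = pd.DataFrame({"const": np.ones(30), "a": np.arange(30.0)})
        X["a_copy"] = X["a"]
        with pytest.raises(EpiError, match="a"):
            fit_linear(X, np.arange(30.0))


class TestOrdinal:
    @staticmethod
    def _proportional_odds_sample(n=4000, beta=0.6, seed=8):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n).astype(float)
        # latent logistic with ordered thresholds
        latent = beta * x + rng.logistic(size=n)
        cuts = np.array([-1.0, 0.5, 2.0])
        y = (latent[:, None] > cuts[None, :]).sum(axis=1)
        return pd.DataFrame({"x": x}), y

    def test_too_few_levels_suggests_binary(self):
        X = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10)]})
        with pytest.raises(EpiError, match="binary"):
            fit_ordinal_logistic(X, np.r_[np.zeros(10), np.ones(10)])

    def test_cutpoints_strictly_increasing_and_beta_recovered(self):
        X, y = self._proportional_odds_sample()
        fit = fit_ordinal_logistic(X, y)
        assert np.all(np.diff(fit.cutpoints) > 0)
        est = fit.term("x")
        assert est["ci_low"] < 0.6 < est["ci_high"]

    def test_collapsed_binary_fit_agrees_under_proportional_odds(self):
        X, y = self._proportional_odds_sample(n=8000, seed=9)
        ordinal = fit_ordinal_logistic(X, y)
        Xb = X.copy()
        Xb.insert(0, "const", 1.0)
        binary = fit_logistic(Xb, (y >= 1).astype(float))
        # same common effect, up to sampling noise of the two estimators
        assert binary.term("x")["estimate"] == pytest.approx(
            ordinal.term("x")["estimate"], abs=0.15
        )


@pytest.fixture(scope="module")
def cohort_and_scores():
    frame, truth = generate_cohort(
        CohortParams(n_patients=400, seed=5), as_records=False
    )
    return frame, truth["score"]


class TestBuildDesign:

    def test_adjustment_ladder_is_nested(self, cohort_and_scores):
        frame, scores = cohort_and_scores
        cols = {}
        for model in ("unadjusted", "model1_age_sex",
                      "model2_plus_marital_employment",
                      "model3_plus_delusions_depression"):
            spec = DesignSpec(model=model)
            cols[model] = set(build_design(frame, scores, spec).columns)
        assert cols["unadjusted"] <= cols["model1_age_sex"]
        assert cols["model1_age_sex"] <= cols["model2_plus_marital_employment"]
        assert cols["model2_plus_marital_employment"] <= cols["model3_plus_delusions_depression"]

    def test_missing_covariate_becomes_indicator_level(self):
        records = [
            PatientRecord("p1", age_years=30, gender="male", marital_status=None,
                          employment="unemployed"),
            PatientRecord("p2", age_years=25, gender="male", marital_status="single",
                          employment="unemployed"),
            PatientRecord("p3", age_years=45, gender="female",
                          marital_status="married_cohabiting", employment="unemployed"),
        ]
        X = build_design(
            records, {"p1": 3, "p2": 0, "p3": 1},
            DesignSpec(model="model2_plus_marital_employment"),
        )
        assert X.loc["p1", "marital_missing"] == 1.0
        assert X.loc["p1", "marital_married_cohabiting"] == 0.0
        assert X.loc["p2", "marital_missing"] == 0.0

    def test_honos_binarised_at_two(self):
        records = [
            PatientRecord("p1", age_years=30, gender="male", honos_depression=2,
                          honos_psychotic=1, marital_status="single",
                          employment="unemployed"),
            PatientRecord("p2", age_years=25, gender="male", honos_depression=1,
                          honos_psychotic=4, marital_status="single",
                          employment="unemployed"),
        ]
        frame = cohort_frame(records)
        assert frame.loc["p1", "depression"] == 1.0
        assert frame.loc["p2", "depression"] == 0.0
        assert frame.loc["p2", "delusions"] == 1.0

    def test_interaction_adds_exactly_two_columns(self, cohort_and_scores):
        frame, scores = cohort_and_scores
        base = build_design(frame, scores, DesignSpec())
        inter = build_design(frame, scores, DesignSpec(age_interaction=True))
        extra = set(inter.columns) - set(base.columns)
        assert extra == {"age_lt40", "age_lt40_x_exposure"}

    def test_score_exposure_uses_raw_scale(self, cohort_and_scores):
        frame, scores = cohort_and_scores
        X = build_design(frame, scores, DesignSpec(exposure="score_per_unit"))
        assert (X["exposure"] == scores.astype(float)).all()


class TestOutcomes:
    @staticmethod
    def _patient(admissions):
        return PatientRecord("p1", age_years=40, gender="male", admissions=admissions)

    def test_admission_and_length_derivation(self):
        out = outcome_builder(
            [self._patient([(dt.date(2011, 3, 1), dt.date(2011, 3, 15))])]
        )
        row = out.loc["p1"]
        assert row["admitted_in_window"] == 1.0
        assert row["first_admission_length_days"] == 14.0

    @pytest.mark.parametrize(
        "next_admit,expected",
        [(dt.date(2012, 6, 29), 1.0), (dt.date(2012, 7, 1), 0.0)],
    )
    def test_readmission_365_day_boundary(self, next_admit, expected):
        admissions = [
            (dt.date(2011, 6, 1), dt.date(2011, 6, 30)),
            (next_admit, next_admit + dt.timedelta(days=10)),
        ]
        out = outcome_builder([self._patient(admissions)])
        assert out.loc["p1", "readmitted_within_365d"] == expected

    def test_no_admissions_yields_nan_outcomes(self):
        out = outcome_builder([self._patient([])])
        row = out.loc["p1"]
        assert row["admitted_in_window"] == 0.0
        assert np.isnan(row["first_admission_length_days"])
        assert np.isnan(row["readmitted_within_365d"])

    def test_overlapping_intervals_merged_with_warning(self):
        admissions = [
            (dt.date(2011, 2, 1), dt.date(2011, 3, 1)),
            (dt.date(2011, 2, 20), dt.date(2011, 4, 1)),
        ]
        with pytest.warns(UserWarning, match="overlapping"):
            out = outcome_builder([self._patient(admissions)])
        assert out.loc["p1", "first_admission_length_days"] == pytest.approx(
            (dt.date(2011, 4, 1) - dt.date(2011, 2, 1)).days
        )


def test_select_nearest_breaks_ties_toward_earlier():
    obs = [(dt.date(2010, 12, 30), "early"), (dt.date(2011, 1, 3), "late"),
           (dt.date(2010, 6, 1), "far")]
    assert select_nearest(obs, dt.date(2011, 1, 1)) == "early"
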