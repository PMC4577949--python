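"""Synthetic cohort generator: determinism, marginals, planted mentions, outcomes."""

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from crisnss.corpus import SYMPTOMS
from crisnss.epi import build_design, fit_logistic
from crisnss.extractor import extract_patient_flags
from crisnss.lexicon import Lexicon, RuleSet
from crisnss.simulate import (
    CohortParams,
    NoteParams,
    _DESIGN_SPEC_M3,
    calibrate_intercepts,
    end_to_end_fixture,
    generate_cohort,
    generate_notes,
    simulate_admission,
    simulate_los,
)
from crisnss.svm import LinearModel


class TestGenerateCohort:
    def test_same_params_and_seed_are_identical(self):
        p = CohortParams(n_patients=80, seed=21)
        r1, t1 = generate_cohort(p)
        r2, t2 = generate_cohort(p)
        assert r1 == r2
        pd.testing.assert_frame_equal(t1, t2)

    def test_single_patient_cohort_is_valid(self):
        records, truth = generate_cohort(CohortParams(n_patients=1, seed=0))
        assert len(records) == 1 and len(truth) == 1
        assert records[0].age_years >= 16

    def test_male_proportion_matches_reference_marginal(self):
        records, _ = generate_cohort(CohortParams(n_patients=7678, seed=2))
        male = sum(r.gender == "male" for r in records) / len(records)
        assert male == pytest.approx(4592 / 7676, abs=0.02)

    def test_symptom_marginals_track_calibration_targets(self):
        p = CohortParams(n_patients=20_000, seed=3)
        _, truth = generate_cohort(p, as_records=False)
        for s in SYMPTOMS:
            target = p.symptom_prevalence_pct[s] / 100
            assert truth[s].mean() == pytest.approx(target, abs=0.02)

    def test_invalid_marginals_rejected(self):
        bad = {"age_band": {"16_19": 0.5, "20_29": 0.2}}
        with pytest.raises(ValueError, match="summing to 1"):
            CohortParams(marginals={**CohortParams().marginals, **bad})

    def test_calibrated_intercepts_reproduce_marginal_prevalence(self):
        # quadrature identity, independent of sampling
        from scipy.special import expit, roots_hermitenorm

        prev = np.array([0.05, 0.30, 0.50])
        a = calibrate_intercepts(prev, loading=1.7)
        z, w = roots_hermitenorm(60)
        w = w / w.sum()
        back = [(w * expit(ai + 1.7 * z)).sum() for ai in a]
        np.testing.assert_allclose(back, prev, atol=1e-8)


class TestGenerateNotes:
    @staticmethod
    def _flags(true_symptoms):
        return pd.Series({s: s in true_symptoms for s in SYMPTOMS})

    def test_true_flag_with_rate_one_always_affirmed(self):
        rng = np.random.default_rng(5)
        params = NoteParams(affirmed_rate=1.0, negated_rate=0.0, family_rate=0.0,
                            irrelevant_rate=0.0)
        docs, spans = generate_notes("p1", self._flags({"apathy"}), params, rng)
        affirmed = [s for s in spans if s.polarity == "affirmed"]
        assert affirmed and all(s.symptom == "apathy" for s in affirmed)
        by_id = {d.doc_id: d for d in docs}
        for s in affirmed:
            assert by_id[s.doc_id].text[s.start:s.end] == "apathy"

    def test_false_flag_with_negation_rate_one_yields_only_negated(self):
        rng = np.random.default_rng(6)
        params = NoteParams(affirmed_rate=1.0, negated_rate=1.0, family_rate=0.0,
                            irrelevant_rate=0.0)
        docs, spans = generate_notes("p1", self._flags(set()), params, rng)
        assert spans and all(s.polarity == "negated" for s in spans)

    def test_gold_spans_index_planted_cue_exactly(self):
        rng = np.random.default_rng(7)
        docs, spans = generate_notes(
            "p1", self._flags({"mute", "poor_rapport"}), NoteParams(), rng,
            gender="female",
        )
        by_id = {d.doc_id: d for d in docs}
        from crisnss.simulate import GENERATION_CUE

        for s in spans:
            assert by_id[s.doc_id].text[s.start:s.end] == GENERATION_CUE[s.symptom]

    def test_note_dates_fall_in_configured_window(self):
        rng = np.random.default_rng(8)
        params = NoteParams(date_start=dt.date(2009, 1, 1),
                            date_end=dt.date(2009, 12, 31))
        docs, _ = generate_notes("p1", self._flags({"apathy"}), params, rng)
        for d in docs:
            assert dt.date(2009, 1, 1) <= d.date <= dt.date(2009, 12, 31)


class TestOutcomes:
    def test_los_never_below_one_day(self):
        p = CohortParams(n_patients=3000, seed=9)
        frame, truth = generate_cohort(p, as_records=False)
        X = build_design(frame, truth["score"], _DESIGN_SPEC_M3)
        rng = np.random.default_rng(1)
        los = simulate_los(X, dataclasses.replace(p.outcomes, los_intercept_days=5.0),
                           rng)
        assert los.min() >= 1.0

    def test_null_admission_effect_ci_covers_unity(self):
        p = CohortParams(n_patients=2000, seed=10)
        null = dataclasses.replace(p.outcomes, admission_or=1.0)
        covered = 0
        reps = 20
        for i in range(reps):
            frame, truth = generate_cohort(p, seed=100 + i, as_records=False)
            X = build_design(frame, truth["score"], _DESIGN_SPEC_M3)
            rng = np.random.default_rng(200 + i)
            y = simulate_admission(X, null, rng)
            term = fit_logistic(X, y).term("exposure")
            covered += term["or_ci_low"] <= 1.0 <= term["or_ci_high"]
        assert covered >= 0.85 * reps


@pytest.fixture(scope="module")
def bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    params = CohortParams(
        n_patients=60, seed=33,
        notes=NoteParams(affirmed_rate=1.0, negated_rate=0.3, family_rate=0.2,
                         irrelevant_rate=0.0),
    )
    manifest = end_to_end_fixture(params, out)
    return params, out, manifest


class TestEndToEnd:

    def test_bundle_files_parse_cleanly(self, bundle):
        from crisnss.corpus import read_annotations, read_cohort_table, read_corpus

        _, out, manifest = bundle
        docs = read_corpus(out / "docs.jsonl")
        spans = read_annotations(out / "gold.ann", docs)
        records = read_cohort_table(out / "cohort.csv", out / "admissions.csv")
        assert len(docs) == manifest["n_documents"]
        assert len(spans) == manifest["n_annotations"]
        assert len(records) == 60

    def test_perfect_grammar_extraction_recovers_planted_flags(self, bundle):
        import json

        from crisnss.corpus import read_corpus

        _, out, _ = bundle
        docs = read_corpus(out / "docs.jsonl")
        truth = json.loads((out / "truth.json").read_text())
        by_patient: dict[str, list] = {}
        for d in docs:
            by_patient.setdefault(d.patient_id, []).append(d)
        affirm = LinearModel(vocabulary={}, weights=np.zeros(0), bias=1.0)
        lexicon, rules = Lexicon.default(), RuleSet()
        for pid, patient_docs in by_patient.items():
            flags = extract_patient_flags(patient_docs, affirm, rules, lexicon)
            assert flags == truth[pid]["flags"], pid

    def test_manifest_hash_changes_iff_params_change(self, bundle):
        params, _, manifest = bundle
        assert params.param_hash() == manifest["param_hash"]
        tweaked = dataclasses.replace(params, seed=34)
        assert tweaked.param_hash() != manifest["param_hash"]
        same = dataclasses.replace(params)
        assert same.param_hash() == manifest["param_hash"]
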