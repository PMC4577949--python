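"""Seeded synthetic EHR cohort generator.

Emulates the study conditions of a large psychiatric case register:
demographics drawn from the reference cohort's marginal distributions
(including realistic missingness), ten binary negative-symptom flags driven
by a shared latent severity factor (which induces the inter-item correlation
a composite scale needs), templated correspondence-style clinical notes
containing affirmed, negated, family-attributed and topically-irrelevant
symptom mentions with gold-standard standoff annotations, and admission /
readmission / length-of-stay outcomes generated from logistic and linear
models with known planted effect sizes.

What the generator does *not* emulate: free-text linguistic variety,
correlation between demographic factors (they are drawn independently), or
the skewness of real length-of-stay distributions (Gaussian noise clipped at
one day; a log-normal option is available).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit, roots_hermitenorm

from . import reference
from .corpus import (
    SYMPTOMS,
    AnnotationSpan,
    Document,
    PatientRecord,
    write_annotations,
    write_cohort_table,
    write_corpus,
)
from .epi import DesignSpec, build_design, cohort_frame

# ---------------------------------------------------------------------------
# parameters


def _marginals_with_missing(sizes: dict[str, int], total: int) -> dict[str, float]:
    known = sum(sizes.values())
    probs = {k: v / total for k, v in sizes.items()}
    if known < total:
        probs["__missing__"] = (total - known) / total
    return probs


def default_marginals() -> dict[str, dict[str, float]]:
    n = reference.N_COHORT
    gs = reference.GROUP_SIZES
    return {
        "age_band": {k: v / sum(gs["age_band"].values()) for k, v in gs["age_band"].items()},
        "gender": {k: v / sum(gs["gender"].values()) for k, v in gs["gender"].items()},
        "marital_status": _marginals_with_missing(gs["marital_status"], n),
        "employment": _marginals_with_missing(gs["employment"], n),
        "adl": _marginals_with_missing(gs["adl"], n),
        "social": _marginals_with_missing(gs["social"], n),
        "delusions": _marginals_with_missing(gs["delusions"], n),
        "depression": _marginals_with_missing(gs["depression"], n),
    }


@dataclass(frozen=True)
class NoteParams:
    """Controls the templated note corpus planted for each patient."""

    notes_per_patient_mean: float = 3.0  # Poisson mean, plus one guaranteed note
    affirmed_rate: float = 0.9    # per note, per true symptom
    negated_rate: float = 0.15    # per note, per false symptom
    family_rate: float = 0.05     # per note, per false symptom
    irrelevant_rate: float = 0.05  # per note, per symptom (topical mentions)
    distractor_rate: float = 0.7  # per note: symptom-free filler sentence
    date_start: dt.date = dt.date(2008, 1, 1)
    date_end: dt.date = dt.date(2010, 12, 31)


@dataclass(frozen=True)
class OutcomeParams:
    """Planted outcome model; effect sizes default to the reference study's
    fully-adjusted estimates so recovery tests target published values."""

    admission_intercept: float = logit(0.18)
    admission_or: float = reference.EFFECT_ADMISSION_OR
    readmission_intercept: float = logit(0.25)
    readmission_or: float = reference.EFFECT_READMISSION_OR
    los_intercept_days: float = 60.0
    los_beta_days: float = reference.EFFECT_LOS_DAYS
    los_noise_sd: float = 30.0
    los_noise: str = "gaussian"  # or "lognormal"
    admission_covariate_effects: dict[str, float] = field(
        default_factory=lambda: {
            "gender_female": -0.2, "age_16_19": 0.2, "age_70_plus": -0.4,
            "marital_married_cohabiting": -0.1, "employment_employed": -0.3,
            "delusions": 0.4, "depression": 0.2,
        }
    )
    readmission_covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"gender_female": -0.1, "delusions": 0.3}
    )
    los_covariate_effects: dict[str, float] = field(
        default_factory=lambda: {
            "gender_female": -4.0, "delusions": 10.0, "age_70_plus": 8.0,
        }
    )


@dataclass(frozen=True)
class CohortParams:
    """Generator configuration; defaults are the reference study conditions."""

    n_patients: int = reference.N_COHORT
    latent_loading: float = 1.7
    symptom_prevalence_pct: dict[str, float] = field(
        default_factory=lambda: dict(reference.SYMPTOM_PREVALENCE_PCT)
    )
    #: per-symptom log-odds shifts by demographic level (applied centred)
    female_symptom_effect: float = -0.35
    age_symptom_effects: dict[str, float] = field(
        default_factory=lambda: {
            "16_19": -0.6, "20_29": 0.0, "30_39": -0.15, "40_49": -0.3,
            "50_59": -0.5, "60_69": -0.8, "70_plus": -1.2,
        }
    )
    marginals: dict[str, dict[str, float]] = field(default_factory=default_marginals)
    notes: NoteParams = field(default_factory=NoteParams)
    outcomes: OutcomeParams = field(default_factory=OutcomeParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for factor, probs in self.marginals.items():
            total = sum(probs.values())
            if any(p < 0 or p > 1 for p in probs.values()) or abs(total - 1.0) > 1e-9:
                raise ValueError(f"marginals for {factor!r} must be probabilities summing to 1")
        for s in SYMPTOMS:
            if s not in self.symptom_prevalence_pct:
                raise ValueError(f"missing symptom prevalence for {s!r}")

    def param_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# symptom-model calibration

_GH_NODES, _GH_WEIGHTS = roots_hermitenorm(40)
_GH_W = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def calibrate_intercepts(prevalence: Sequence[float], loading: float) -> np.ndarray:
    """Per-symptom intercepts a_i such that the marginal P(flag) over a
    standard-normal latent severity z, P = E[expit(a + loading*z)], matches
    each target prevalence (solved by bisection on Gauss-Hermite quadrature).
    """
    out = np.empty(len(prevalence))
    for i, p in enumerate(prevalence):
        f = lambda a: float((_GH_W * expit(a + loading * _GH_NODES)).sum()) - p
        out[i] = brentq(f, -25.0, 25.0)
    return out


# ---------------------------------------------------------------------------
# cohort generation

_AGE_RANGES = {
    "16_19": (16, 19), "20_29": (20, 29), "30_39": (30, 39), "40_49": (40, 49),
    "50_59": (50, 59), "60_69": (60, 69), "70_plus": (70, 90),
}


def _draw_categorical(rng: np.random.Generator, probs: dict[str, float], n: int) -> np.ndarray:
    levels = sorted(probs)
    p = np.array([probs[l] for l in levels])
    return np.array(levels, dtype=object)[rng.choice(len(levels), size=n, p=p / p.sum())]


def generate_cohort(
    params: CohortParams, seed: int | None = None, as_records: bool = True
) -> tuple[list[PatientRecord] | pd.DataFrame, pd.DataFrame]:
    """Draw demographics and true symptom flags; deterministic given seed.

    Returns ``(cohort, truth)`` where *cohort* is a list of
    :class:`PatientRecord` (or, with ``as_records=False``, the covariate
    DataFrame consumed by :func:`crisnss.epi.build_design`) and *truth* holds
    the planted per-patient flags, composite score and latent severity.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_patients
    pids = [f"P{i:06d}" for i in range(n)]

    draws = {
        factor: _draw_categorical(rng, params.marginals[factor], n)
        for factor in ("age_band", "gender", "marital_status", "employment",
                       "adl", "social", "delusions", "depression")
    }
    ages = np.array(
        [rng.integers(*_AGE_RANGES[b], endpoint=True) for b in draws["age_band"]]
    )

    # symptom flags from the latent-severity logit model, with centred
    # demographic shifts so calibrated marginals are preserved
    prev = np.array([params.symptom_prevalence_pct[s] for s in SYMPTOMS]) / 100.0
    intercepts = calibrate_intercepts(prev, params.latent_loading)
    female = (draws["gender"] == "female").astype(float)
    p_female = params.marginals["gender"]["female"]
    age_eff = np.array([params.age_symptom_effects[b] for b in draws["age_band"]])
    mean_age_eff = sum(
        params.age_symptom_effects[b] * p
        for b, p in params.marginals["age_band"].items()
    )
    offset = (
        params.female_symptom_effect * (female - p_female) + (age_eff - mean_age_eff)
    )
    z = rng.standard_normal(n)
    eta = intercepts[None, :] + params.latent_loading * z[:, None] + offset[:, None]
    flags = rng.random((n, len(SYMPTOMS))) < expit(eta)

    truth = pd.DataFrame(flags, index=pids, columns=list(SYMPTOMS))
    truth["score"] = truth[list(SYMPTOMS)].sum(axis=1)
    truth["latent_severity"] = z
    truth.index.name = "patient_id"

    def honos(level: object, r: np.random.Generator) -> int | None:
        if level == "__missing__":
            return None
        return int(r.integers(2, 5)) if level == "present" else int(r.integers(0, 2))

    if as_records:
        records = []
        for i, pid in enumerate(pids):
            records.append(
                PatientRecord(
                    patient_id=pid,
                    age_years=int(ages[i]),
                    gender=str(draws["gender"][i]),
                    marital_status=None if draws["marital_status"][i] == "__missing__"
                    else str(draws["marital_status"][i]),
                    employment=None if draws["employment"][i] == "__missing__"
                    else str(draws["employment"][i]),
                    honos_adl=honos(draws["adl"][i], rng),
                    honos_social=honos(draws["social"][i], rng),
                    honos_psychotic=honos(draws["delusions"][i], rng),
                    honos_depression=honos(draws["depression"][i], rng),
                )
            )
        return records, truth

    frame = pd.DataFrame(
        {
            "age_band": draws["age_band"],
            "gender": draws["gender"],
            "marital_status": draws["marital_status"],
            "employment": draws["employment"],
            "adl": [None if v == "__missing__" else float(v == "present") for v in draws["adl"]],
            "social": [None if v == "__missing__" else float(v == "present") for v in draws["social"]],
            "delusions": [None if v == "__missing__" else float(v == "present") for v in draws["delusions"]],
            "depression": [None if v == "__missing__" else float(v == "present") for v in draws["depression"]],
        },
        index=pd.Index(pids, name="patient_id"),
    )
    for col in ("marital_status", "employment"):
        frame[col] = frame[col].replace("__missing__", None)
    return frame, truth


# ---------------------------------------------------------------------------
# note generation

GENERATION_CUE = {
    "poor_motivation": "poor motivation",
    "blunted_affect": "blunted affect",
    "poor_eye_contact": "poor eye contact",
    "emotional_withdrawal": "emotional withdrawal",
    "poor_rapport": "poor rapport",
    "social_withdrawal": "social withdrawal",
    "poverty_of_speech": "poverty of speech",
    "mute": "mutism",
    "apathy": "apathy",
    "concrete_thinking": "concrete thinking",
}

AFFIRMED_TEMPLATES = (
    "On review {subj} displays {cue} throughout the interview.",
    "There is marked {cue} at today's assessment.",
    "Staff describe persistent {cue} over recent weeks.",
    "{subj_cap} presents with {cue} and reduced engagement in ward activities.",
)
NEGATED_TEMPLATES = (
    "{subj_cap} denies {cue} at present.",
    "There is no {cue} on examination today.",
    "{subj_cap} reports no {cue} since the last review.",
    "Nil {cue} observed during this admission.",
)
FAMILY_TEMPLATES = (
    "{poss_cap} mother describes {cue} at home.",
    "{poss_cap} sister mentioned {cue} when contacted.",
    "Family report {cue} over the past year.",
)
IRRELEVANT_TEMPLATES = (
    "The psychoeducation group discussed {cue} and coping strategies.",
    "Leaflet about {cue} provided for information.",
    "The ward round considered {cue} in general terms only.",
)
DISTRACTOR_SENTENCES = (
    "Medication was reviewed and continues unchanged.",
    "Attended the outpatient clinic accompanied by a support worker.",
    "Sleep and appetite remain satisfactory.",
    "Plan to follow up in six weeks at the community clinic.",
    "Physical observations were within normal limits.",
)

_POLARITY_OF_TEMPLATE = {"affirmed": "affirmed", "negated": "negated",
                         "family": "irrelevant", "irrelevant": "irrelevant"}


def _render(template: str, symptom: str, gender: str | None) -> tuple[str, int, int]:
    """Fill a template; return (sentence, cue_start, cue_end)."""
    subj = "she" if gender == "female" else "he"
    poss = "her" if gender == "female" else "his"
    cue = GENERATION_CUE[symptom]
    sentence = template.format(
        cue=cue, subj=subj, subj_cap=subj.capitalize(), poss_cap=poss.capitalize()
    )
    start = sentence.index(cue)
    return sentence, start, start + len(cue)


def generate_notes(
    patient_id: str,
    flags: pd.Series,
    params: NoteParams,
    rng: np.random.Generator,
    gender: str | None = None,
    doc_prefix: str = "",
) -> tuple[list[Document], list[AnnotationSpan]]:
    """Templated notes for one patient, with gold standoff annotations.

    Every true flag is documented with affirmed mentions at the configured
    per-note rate; false flags attract spurious negated / family-attributed
    mentions; topical (irrelevant) mentions occur for any symptom.
    """
    n_notes = 1 + int(rng.poisson(params.notes_per_patient_mean))
    span_days = (params.date_end - params.date_start).days
    docs: list[Document] = []
    spans: list[AnnotationSpan] = []
    for j in range(n_notes):
        doc_id = f"{doc_prefix}{patient_id}_d{j:02d}"
        sentences: list[tuple[str, str | None, int, int]] = []  # text, sym, cs, ce

        def plant(kind: str, templates: tuple[str, ...], symptom: str) -> None:
            t = templates[int(rng.integers(len(templates)))]
            sent, cs, ce = _render(t, symptom, gender)
            sentences.append((sent, f"{symptom}:{_POLARITY_OF_TEMPLATE[kind]}", cs, ce))

        sentences.append(("Seen for routine clinical review.", None, 0, 0))
        for symptom in SYMPTOMS:
            if flags[symptom]:
                if rng.random() < params.affirmed_rate:
                    plant("affirmed", AFFIRMED_TEMPLATES, symptom)
            else:
                if rng.random() < params.negated_rate:
                    plant("negated", NEGATED_TEMPLATES, symptom)
                if rng.random() < params.family_rate:
                    plant("family", FAMILY_TEMPLATES, symptom)
            if rng.random() < params.irrelevant_rate:
                plant("irrelevant", IRRELEVANT_TEMPLATES, symptom)
        if rng.random() < params.distractor_rate:
            sentences.append(
                (DISTRACTOR_SENTENCES[int(rng.integers(len(DISTRACTOR_SENTENCES)))],
                 None, 0, 0)
            )

        text_parts: list[str] = []
        offset = 0
        for sent, tag, cs, ce in sentences:
            if tag is not None:
                symptom, polarity = tag.split(":")
                spans.append(
                    AnnotationSpan(
                        doc_id=doc_id, start=offset + cs, end=offset + ce,
                        symptom=symptom, polarity=polarity,
                    )
                )
            text_parts.append(sent)
            offset += len(sent) + 1  # single joining space
        date = params.date_start + dt.timedelta(days=int(rng.integers(span_days + 1)))
        docs.append(
            Document(
                doc_id=doc_id, patient_id=patient_id, date=date,
                text=" ".join(text_parts), source="correspondence",
            )
        )
    return docs, spans


def generate_labelled_instance_corpus(
    n_per_symptom: int = 200,
    pos_frac: float = 0.5,
    positive_label_noise: float = 0.0,
    seed: int = 0,
    negative_kinds: tuple[str, ...] = ("negated", "family", "irrelevant"),
) -> tuple[list[Document], list[AnnotationSpan]]:
    """Single-sentence documents for classifier evaluation.

    Half the instances per symptom are affirmed (gold positive), the rest
    cycle through *negative_kinds* wordings (gold not-positive). Negated and
    family-attributed negatives follow the deterministic rule grammar;
    topically-irrelevant ones (symptom discussed, not exhibited) are the
    statistically-learned part — drop ``"irrelevant"`` from *negative_kinds*
    for a corpus whose grammar decides every instance exactly.
    ``positive_label_noise`` is the fraction of gold-positive instances whose
    *text* is written in negated form while the gold label stays affirmed —
    i.e. annotation noise on positives.
    """
    rng = np.random.default_rng(seed)
    docs: list[Document] = []
    spans: list[AnnotationSpan] = []
    k = 0
    for symptom in SYMPTOMS:
        n_pos = int(round(n_per_symptom * pos_frac))
        for i in range(n_per_symptom):
            positive = i < n_pos
            if positive and rng.random() < positive_label_noise:
                templates, polarity = NEGATED_TEMPLATES, "affirmed"
            elif positive:
                templates, polarity = AFFIRMED_TEMPLATES, "affirmed"
            else:
                kind = negative_kinds[i % len(negative_kinds)]
                templates = {"negated": NEGATED_TEMPLATES, "family": FAMILY_TEMPLATES,
                             "irrelevant": IRRELEVANT_TEMPLATES}[kind]
                polarity = _POLARITY_OF_TEMPLATE[kind]
            gender = "female" if rng.random() < 0.5 else "male"
            sent, cs, ce = _render(templates[int(rng.integers(len(templates)))],
                                   symptom, gender)
            doc_id = f"I{k:06d}"
            k += 1
            docs.append(
                Document(doc_id=doc_id, patient_id=doc_id, text=sent,
                         date=dt.date(2010, 6, 1))
            )
            spans.append(
                AnnotationSpan(doc_id=doc_id, start=cs, end=ce,
                               symptom=symptom, polarity=polarity)
            )
    return docs, spans


# ---------------------------------------------------------------------------
# outcome generation

_DESIGN_SPEC_M3 = DesignSpec(outcome="binary", exposure="binary_ge2",
                             model="model3_plus_delusions_depression")


def _linear_predictor(
    X: pd.DataFrame, intercept: float, exposure_effect: float,
    covariate_effects: dict[str, float],
) -> np.ndarray:
    eta = np.full(len(X), intercept, dtype=float)
    eta += exposure_effect * X["exposure"].to_numpy()
    for col, beta in covariate_effects.items():
        if col in X.columns:
            eta += beta * X[col].to_numpy()
    return eta


def simulate_admission(
    X: pd.DataFrame, params: OutcomeParams, rng: np.random.Generator
) -> np.ndarray:
    eta = _linear_predictor(X, params.admission_intercept,
                            math.log(params.admission_or),
                            params.admission_covariate_effects)
    return (rng.random(len(X)) < expit(eta)).astype(float)


def simulate_readmission(
    X: pd.DataFrame, params: OutcomeParams, rng: np.random.Generator
) -> np.ndarray:
    eta = _linear_predictor(X, params.readmission_intercept,
                            math.log(params.readmission_or),
                            params.readmission_covariate_effects)
    return (rng.random(len(X)) < expit(eta)).astype(float)


def simulate_los(
    X: pd.DataFrame, params: OutcomeParams, rng: np.random.Generator
) -> np.ndarray:
    mu = _linear_predictor(X, params.los_intercept_days, params.los_beta_days,
                           params.los_covariate_effects)
    if params.los_noise == "lognormal":
        sigma = params.los_noise_sd / params.los_intercept_days
        y = mu * rng.lognormal(-0.5 * sigma**2, sigma, size=len(X))
    else:
        y = mu + rng.normal(0.0, params.los_noise_sd, size=len(X))
    return np.maximum(y, 1.0)  # stays at least one day


def generate_outcomes(
    records: Sequence[PatientRecord],
    truth: pd.DataFrame,
    params: CohortParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Admission, readmission and LOS outcomes; admissions are also written
    into each record's admission-interval list so the outcome builder can
    re-derive them from dates."""
    cohort = cohort_frame(records)
    X = build_design(cohort, truth["score"], _DESIGN_SPEC_M3)
    admitted = simulate_admission(X, params.outcomes, rng)
    los = simulate_los(X, params.outcomes, rng)
    readm = simulate_readmission(X, params.outcomes, rng)

    out = pd.DataFrame(index=cohort.index)
    out["admitted"] = admitted
    out["los_days"] = np.where(admitted == 1.0, los, np.nan)
    out["readmitted"] = np.nan
    for i, r in enumerate(records):
        if admitted[i] != 1.0:
            continue
        admit = dt.date(2011, 1, 1) + dt.timedelta(days=int(rng.integers(0, 240)))
        discharge = admit + dt.timedelta(days=int(round(los[i])))
        r.admissions.append((admit, discharge))
        if discharge <= dt.date(2011, 12, 31):
            out.iloc[i, out.columns.get_loc("readmitted")] = readm[i]
            if readm[i] == 1.0:
                gap = int(rng.integers(5, 360))
                re_admit = discharge + dt.timedelta(days=gap)
                re_dis = re_admit + dt.timedelta(days=int(round(
                    max(1.0, rng.normal(params.outcomes.los_intercept_days,
                                        params.outcomes.los_noise_sd)))))
                r.admissions.append((re_admit, re_dis))
    return out


# ---------------------------------------------------------------------------
# end-to-end bundle

def end_to_end_fixture(params: CohortParams, out_dir: str | Path) -> dict:
    """Emit every input file the pipeline consumes, internally consistent.

    Writes docs.jsonl, gold.ann, cohort.csv, admissions.csv, truth.json and
    manifest.json under *out_dir*; returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq = np.random.SeedSequence(params.seed)
    rng_cohort, rng_notes, rng_outcomes = (
        np.random.default_rng(s) for s in seq.spawn(3)
    )
    records, truth = generate_cohort(params, seed=int(rng_cohort.integers(2**31)))
    all_docs: list[Document] = []
    all_spans: list[AnnotationSpan] = []
    for r in records:
        docs, spans = generate_notes(
            r.patient_id, truth.loc[r.patient_id], params.notes, rng_notes,
            gender=r.gender,
        )
        all_docs.extend(docs)
        all_spans.extend(spans)
    outcomes = generate_outcomes(records, truth, params, rng_outcomes)

    write_corpus(all_docs, out / "docs.jsonl")
    write_annotations(all_spans, all_docs, out / "gold.ann")
    write_cohort_table(records, out / "cohort.csv", out / "admissions.csv")
    truth_payload = {
        pid: {
            "flags": {s: bool(truth.loc[pid, s]) for s in SYMPTOMS},
            "score": int(truth.loc[pid, "score"]),
            "admitted": None if np.isnan(outcomes.loc[pid, "admitted"])
            else bool(outcomes.loc[pid, "admitted"]),
            "readmitted": None if np.isnan(outcomes.loc[pid, "readmitted"])
            else bool(outcomes.loc[pid, "readmitted"]),
            "los_days": None if np.isnan(outcomes.loc[pid, "los_days"])
            else float(outcomes.loc[pid, "los_days"]),
        }
        for pid in truth.index
    }
    (out / "truth.json").write_text(json.dumps(truth_payload, indent=1))
    manifest = {
        "seed": params.seed,
        "param_hash": params.param_hash(),
        "n_patients": params.n_patients,
        "n_documents": len(all_docs),
        "n_annotations": len(all_spans),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# parameter recovery

def parameter_recovery(
    n_replicates: int = 200,
    seed: int = 1,
    params: CohortParams | None = None,
    n_admission: int = reference.N_COHORT,
    n_readmission: int = reference.N_DISCHARGED,
    n_los: int = reference.N_INPATIENT,
) -> pd.DataFrame:
    """Coverage study: regenerate cohorts and refit the fully-adjusted designs.

    For each replicate a fresh cohort is drawn, the three outcomes are
    generated at the planted effect sizes, and the fully-adjusted
    (model 3) regressions are refit; the fraction of replicates whose 95%
    exposure CI covers the generating value estimates the interval coverage
    (nominally 95%, binomial noise ~3% at 200 replicates).
    """
    from .epi import fit_linear, fit_logistic  # local import avoids cycle at import time

    params = params or CohortParams()
    root = np.random.SeedSequence(seed)
    truths = {
        "admission_or": params.outcomes.admission_or,
        "readmission_or": params.outcomes.readmission_or,
        "los_beta_days": params.outcomes.los_beta_days,
    }
    records = {k: {"covered": 0, "fitted": 0, "estimates": []} for k in truths}
    for child in root.spawn(n_replicates):
        s1, s2, s3 = child.spawn(3)
        rng = np.random.default_rng(s1)
        tasks = (
            ("admission_or", n_admission, simulate_admission, fit_logistic, "odds_ratio"),
            ("readmission_or", n_readmission, simulate_readmission, fit_logistic, "odds_ratio"),
            ("los_beta_days", n_los, simulate_los, fit_linear, "estimate"),
        )
        for (key, n, sim, fit, scale), sub in zip(tasks, (s1, s2, s3)):
            rng = np.random.default_rng(sub)
            p = dataclasses.replace(params, n_patients=n)
            frame, truth = generate_cohort(p, seed=int(rng.integers(2**31)),
                                           as_records=False)
            X = build_design(frame, truth["score"], _DESIGN_SPEC_M3)
            y = sim(X, params.outcomes, rng)
            res = fit(X, y)
            term = res.term("exposure")
            if scale == "odds_ratio":
                est, lo, hi = term["odds_ratio"], term["or_ci_low"], term["or_ci_high"]
            else:
                est, lo, hi = term["estimate"], term["ci_low"], term["ci_high"]
            records[key]["fitted"] += 1
            records[key]["estimates"].append(est)
            if lo <= truths[key] <= hi:
                records[key]["covered"] += 1
    rows = []
    for key, rec in records.items():
        rows.append(
            {
                "effect": key,
                "true_value": truths[key],
                "mean_estimate": float(np.mean(rec["estimates"])),
                "coverage_pct": 100.0 * rec["covered"] / rec["fitted"],
                "n_replicates": rec["fitted"],
            }
        )
    return pd.DataFrame(rows).set_index("effect")
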