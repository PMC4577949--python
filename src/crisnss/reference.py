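"""Reference anchors from a large urban secondary-mental-healthcare register
cohort of adults with schizophrenia (n=7678) receiving care during 2011.

These published marginal figures serve two purposes: (1) the synthetic
cohort generator uses them as default demographic marginals, symptom
prevalences and planted effect sizes, so that recovery tests exercise
realistic study conditions; (2) the 2x2 reconstruction analysis recomputes
the published unadjusted odds ratios directly from the printed group sizes
and prevalences.

Each UNADJUSTED_OR_ROWS entry: (factor, level, n_level, prev_level_pct,
n_reference, prev_reference_pct, published_or). Prevalence is the percent of
the group with two or more documented negative symptoms.
"""

from __future__ import annotations

N_COHORT = 7678          # sample A: patients under care during 2011
N_DISCHARGED = 1612      # sample B: discharged from inpatient care in 2011
N_INPATIENT = 1609       # sample C: received inpatient care in 2011
N_CASES_GE2 = 3149       # patients with >=2 negative symptoms documented
PREVALENCE_GE2_PCT = 41.0

#: percent of patients by number of documented symptoms
SCORE_BAND_PCT = {"1": 14.6, "2": 12.7, "3": 9.3, "4": 6.4, "5": 5.0, "6+": 7.6}

#: per-symptom documentation prevalence (percent of cohort), canonical order
SYMPTOM_PREVALENCE_PCT = {
    "poor_motivation": 30.5,
    "blunted_affect": 27.4,
    "poor_eye_contact": 26.0,
    "emotional_withdrawal": 23.5,
    "poor_rapport": 16.3,
    "social_withdrawal": 12.7,
    "poverty_of_speech": 12.4,
    "mute": 8.1,
    "apathy": 7.7,
    "concrete_thinking": 5.7,
}

#: fully-adjusted effect sizes of the >=2-symptom exposure on the outcomes
EFFECT_ADMISSION_OR = 1.24        # inpatient admission during follow-up year
EFFECT_READMISSION_OR = 1.58      # readmission within 12 months of discharge
EFFECT_LOS_DAYS = 20.5            # extra days of first inpatient admission

#: published 95% CI for the female-vs-male unadjusted odds ratio
GENDER_OR_CI = (0.59, 0.71)

UNADJUSTED_OR_ROWS = [
    ("age", "16_19", 203, 27.6, 1337, 52.0, 0.35),
    ("age", "30_39", 1775, 47.0, 1337, 52.0, 0.82),
    ("age", "40_49", 1983, 42.6, 1337, 52.0, 0.69),
    ("age", "50_59", 1137, 37.2, 1337, 52.0, 0.55),
    ("age", "60_69", 654, 29.1, 1337, 52.0, 0.38),
    ("age", "70_plus", 589, 18.0, 1337, 52.0, 0.20),
    ("gender", "female", 3084, 34.7, 4592, 45.3, 0.64),
    ("marital", "married_cohabiting", 785, 31.6, 5795, 44.6, 0.57),
    ("marital", "divorced_separated", 776, 33.4, 5795, 44.6, 0.62),
    ("marital", "widowed", 208, 21.2, 5795, 44.6, 0.33),
    ("employment", "employed", 341, 39.6, 4956, 47.9, 0.71),
    ("employment", "in_education", 311, 39.6, 4956, 47.9, 0.71),
    ("employment", "retired", 7, 14.3, 4956, 47.9, 0.18),
    ("adl", "present", 2283, 46.3, 4700, 41.9, 1.20),
    ("social", "present", 2533, 44.4, 4432, 42.7, 1.07),
    ("delusions", "present", 3077, 45.0, 3904, 41.9, 1.14),
    ("depression", "present", 2014, 38.8, 4976, 45.2, 0.77),
]

#: group sizes by factor level in the reference cohort (used for marginals)
GROUP_SIZES = {
    "age_band": {
        "16_19": 203, "20_29": 1337, "30_39": 1775, "40_49": 1983,
        "50_59": 1137, "60_69": 654, "70_plus": 589,
    },
    "gender": {"male": 4592, "female": 3084},
    "marital_status": {
        "single": 5795, "married_cohabiting": 785,
        "divorced_separated": 776, "widowed": 208,
    },
    "employment": {
        "unemployed": 4956, "employed": 341, "in_education": 311, "retired": 7,
    },
    # HoNOS-derived constructs: number with the construct present / absent
    "adl": {"present": 2283, "absent": 4700},
    "social": {"present": 2533, "absent": 4432},
    "delusions": {"present": 3077, "absent": 3904},
    "depression": {"present": 2014, "absent": 4976},
}
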