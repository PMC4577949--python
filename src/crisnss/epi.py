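"""Epidemiological estimation layer.

Implements the association analyses between negative-symptom exposure and
outcomes: closed-form 2x2 odds ratios with Woolf/Wald confidence intervals,
reconstruction of cell counts from printed group sizes and prevalences,
binary logistic / proportional-odds ordinal logistic / ordinary linear
regression behind a common result type, a nested covariate-adjustment ladder
(unadjusted -> age+sex -> +marital+employment -> +delusions+depression),
missing-indicator coding for incomplete covariates, and derivation of the
admission / readmission / length-of-stay outcomes from admission intervals.

Model fitting delegates to statsmodels; everything structural (design
construction, count reconstruction, closed-form OR, outcome derivation) is
implemented here.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .corpus import PatientRecord

Z95 = 1.959963984540054  # two-sided 95% normal quantile

AGE_BANDS = ("16_19", "20_29", "30_39", "40_49", "50_59", "60_69", "70_plus")
AGE_REFERENCE = "20_29"  # youngest group of sufficient size
MODELS = ("unadjusted", "model1_age_sex", "model2_plus_marital_employment",
          "model3_plus_delusions_depression")


class EpiError(ValueError):
    """Invalid input to the estimation layer."""


# ---------------------------------------------------------------------------
# 2x2 tables

@dataclass(frozen=True)
class ContingencyTable2x2:
    """a: exposed cases, b: exposed non-cases, c: unexposed cases, d: unexposed non-cases."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise EpiError("cell counts must be non-negative")


@dataclass(frozen=True)
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise EpiError("CI must bracket the odds ratio")


def reconstruct_counts(n_group: int, prevalence_pct: float) -> tuple[int, int]:
    """(cases, non_cases) from a printed group size and percent prevalence.

    Rounds half-up; a count reconstructed from a 1-dp prevalence can differ
    from the true count by one.
    """
    if n_group <= 0:
        raise EpiError(f"group size must be positive, got {n_group}")
    if not (0.0 <= prevalence_pct <= 100.0):
        raise EpiError(f"prevalence {prevalence_pct} outside 0-100")
    cases = math.floor(n_group * prevalence_pct / 100.0 + 0.5)
    return cases, n_group - cases


def odds_ratio_2x2(
    table: ContingencyTable2x2, continuity_correction: bool = False
) -> ORResult:
    """Woolf/Wald odds ratio: OR = ad/bc, CI = exp(ln OR +- z * se).

    se = sqrt(1/a + 1/b + 1/c + 1/d); two-sided p from the Wald z statistic.
    Zero cells raise unless *continuity_correction* adds 0.5 to every cell.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        if not continuity_correction:
            raise EpiError("zero cell in 2x2 table; pass continuity_correction=True")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    z = log_or / se
    p = 2.0 * float(norm.sf(abs(z)))
    return ORResult(
        odds_ratio=or_,
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        p_value=max(p, np.nextafter(0, 1)),
    )


# ---------------------------------------------------------------------------
# regression results

@dataclass
class RegressionResult:
    """Fit summary shared by the three model families.

    ``terms`` has one row per parameter: estimate (log-odds, cumulative
    log-odds, or days), se, ci_low, ci_high, p. For logistic families
    ``odds_ratio``/``or_ci_low``/``or_ci_high`` columns are added.
    """

    model_type: str  # "logistic" | "ordinal_logistic" | "linear"
    terms: pd.DataFrame
    n: int
    converged: bool
    cutpoints: np.ndarray | None = None
    warnings_: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]


def _terms_frame(params: pd.Series, bse: pd.Series, exponentiate: bool) -> pd.DataFrame:
    est = params.astype(float)
    se = bse.astype(float)
    z = est / se
    frame = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_low": est - Z95 * se,
            "ci_high": est + Z95 * se,
            "p": 2.0 * norm.sf(np.abs(z)),
        }
    )
    if exponentiate:
        with np.errstate(over="ignore"):  # diverged sparse levels -> inf OR
            frame["odds_ratio"] = np.exp(frame["estimate"])
            frame["or_ci_low"] = np.exp(frame["ci_low"])
            frame["or_ci_high"] = np.exp(frame["ci_high"])
    return frame


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify aliased columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps if diag.size else 0.0
        aliased = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        aliased += [X.columns[j] for j in piv[len(diag):]]
        raise EpiError(f"design matrix is rank deficient; aliased terms: {aliased}")


def fit_logistic(X: pd.DataFrame, y: Sequence[int] | np.ndarray) -> RegressionResult:
    """Maximum-likelihood binary logistic regression (Newton, tol 1e-8)."""
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise EpiError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise EpiError("degenerate outcome: all responses identical")
    if len(y) != len(X):
        raise EpiError("outcome and design lengths differ")
    _check_full_rank(X)
    notes = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X.astype(float))
        try:
            res = model.fit(method="newton", tol=1e-8, maxiter=200, disp=0)
        except np.linalg.LinAlgError:
            # quasi-separated sparse categories make the Newton Hessian
            # singular at the boundary; quasi-Newton still yields finite
            # estimates and standard errors for the regular terms
            res = model.fit(method="bfgs", gtol=1e-8, maxiter=2000, disp=0)
            notes.append("newton failed (singular Hessian); refit with bfgs")
    big = res.params[np.abs(res.params) > 15]
    if len(big):
        notes.append(f"possible separation; diverging terms: {list(big.index)}")
    if not np.all(np.isfinite(res.bse)):
        notes.append("non-finite standard errors for some terms")
    return RegressionResult(
        model_type="logistic",
        terms=_terms_frame(res.params, res.bse, exponentiate=True),
        n=len(y),
        converged=bool(res.mle_retvals.get("converged", True)),
        warnings_=notes,
    )


def fit_ordinal_logistic(
    X: pd.DataFrame, y: Sequence[int] | np.ndarray
) -> RegressionResult:
    """Proportional-odds ordinal logistic regression.

    One common odds ratio per covariate plus strictly increasing cutpoints.
    *X* must not contain a constant column (absorbed by the cutpoints).
    """
    y = np.asarray(y)
    levels = np.unique(y)
    if len(levels) < 3:
        raise EpiError("outcome has <3 observed levels; use binary logistic instead")
    if "const" in X.columns:
        raise EpiError("drop the constant column; cutpoints play that role")
    _check_full_rank(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(y, X.astype(float), distr="logit")
        res = model.fit(method="lbfgs", maxiter=2000, disp=0)
    k_cov = X.shape[1]
    params = res.params.iloc[:k_cov]
    bse = res.bse.iloc[:k_cov]
    cutpoints = model.transform_threshold_params(res.params.to_numpy())[1:-1]
    return RegressionResult(
        model_type="ordinal_logistic",
        terms=_terms_frame(params, bse, exponentiate=True),
        n=len(y),
        converged=bool(res.mle_retvals.get("converged", True)),
        cutpoints=np.asarray(cutpoints, dtype=float),
    )


def fit_linear(X: pd.DataFrame, y: Sequence[float] | np.ndarray) -> RegressionResult:
    """Ordinary least squares; estimates in outcome units (days)."""
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1]:
        raise EpiError("need more observations than parameters")
    _check_full_rank(X)
    res = sm.OLS(y, X.astype(float)).fit()
    return RegressionResult(
        model_type="linear",
        terms=_terms_frame(res.params, res.bse, exponentiate=False),
        n=len(y),
        converged=True,
    )


# ---------------------------------------------------------------------------
# design construction

@dataclass(frozen=True)
class DesignSpec:
    """What goes into the regression design.

    ``model`` selects the nested adjustment ladder; ``exposure`` is either
    the binary >=2-symptoms indicator or the 0-10 score per unit;
    ``missing_as_category`` codes missing covariate values as their own
    indicator level; ``age_interaction`` adds an age<40 indicator and its
    product with the exposure.
    """

    outcome: str = "binary"  # binary | ordinal_0_10 | continuous_days
    exposure: str = "binary_ge2"  # binary_ge2 | score_per_unit
    model: str = "model3_plus_delusions_depression"
    threshold: int = 2
    missing_as_category: bool = True
    age_interaction: bool = False

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise EpiError(f"unknown adjustment model {self.model!r}")
        if self.exposure not in ("binary_ge2", "score_per_unit"):
            raise EpiError(f"unknown exposure {self.exposure!r}")
        if self.outcome not in ("binary", "ordinal_0_10", "continuous_days"):
            raise EpiError(f"unknown outcome {self.outcome!r}")


def age_band(age_years: int | None) -> str | None:
    if age_years is None:
        return None
    if age_years < 16:
        raise EpiError(f"age {age_years} below 16")
    for lo, hi, name in ((16, 19, "16_19"), (20, 29, "20_29"), (30, 39, "30_39"),
                         (40, 49, "40_49"), (50, 59, "50_59"), (60, 69, "60_69")):
        if lo <= age_years <= hi:
            return name
    return "70_plus"


def _dummies(
    series: pd.Series, reference: str, prefix: str, missing_as_category: bool
) -> pd.DataFrame:
    levels = [lv for lv in series.dropna().unique() if lv != reference]
    if reference not in set(series.dropna()):
        raise EpiError(f"reference category {reference!r} absent from {prefix}")
    out = pd.DataFrame(index=series.index)
    for lv in sorted(levels):
        out[f"{prefix}_{lv}"] = (series == lv).astype(float)
    if missing_as_category and series.isna().any():
        out[f"{prefix}_missing"] = series.isna().astype(float)
    return out


def cohort_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten patient records to a covariate DataFrame (HoNOS binarised >=2)."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "age_band": age_band(r.age_years),
                "gender": r.gender,
                "marital_status": r.marital_status,
                "employment": r.employment,
                "adl": None if r.honos_adl is None else float(r.honos_adl >= 2),
                "social": None if r.honos_social is None else float(r.honos_social >= 2),
                "delusions": None if r.honos_psychotic is None else float(r.honos_psychotic >= 2),
                "depression": None if r.honos_depression is None else float(r.honos_depression >= 2),
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


def build_design(
    cohort: pd.DataFrame | Sequence[PatientRecord],
    scores: Mapping[str, int] | pd.Series,
    spec: DesignSpec,
) -> pd.DataFrame:
    """Design matrix for the requested adjustment model.

    Reference categories: the most prevalent level of each factor in the
    reference population (male, single, unemployed, construct absent) except
    age, where 20-29 — the youngest group of sufficient size — is the
    reference. Binary HoNOS-derived covariates enter as present-vs-absent
    indicators; missing values become explicit ``_missing`` levels when
    ``spec.missing_as_category``.
    """
    if not isinstance(cohort, pd.DataFrame):
        cohort = cohort_frame(cohort)
    scores = pd.Series(scores, dtype=float).reindex(cohort.index)
    if scores.isna().any():
        raise EpiError("missing composite score for some patients")

    X = pd.DataFrame(index=cohort.index)
    X["const"] = 1.0
    if spec.exposure == "binary_ge2":
        X["exposure"] = (scores >= spec.threshold).astype(float)
    else:
        X["exposure"] = scores

    mc = spec.missing_as_category
    if spec.model in MODELS[1:]:
        X = X.join(_dummies(cohort["age_band"], AGE_REFERENCE, "age", mc))
        X = X.join(_dummies(cohort["gender"], "male", "gender", mc))
    if spec.model in MODELS[2:]:
        X = X.join(_dummies(cohort["marital_status"], "single", "marital", mc))
        X = X.join(_dummies(cohort["employment"], "unemployed", "employment", mc))
    if spec.model in MODELS[3:]:
        for construct in ("delusions", "depression"):
            col = cohort[construct]
            X[construct] = col.fillna(0.0).astype(float)
            if mc and col.isna().any():
                X[f"{construct}_missing"] = col.isna().astype(float)

    if spec.age_interaction:
        # age<40 indicator and its product with the exposure
        band = cohort["age_band"]
        lt40 = band.isin(["16_19", "20_29", "30_39"]).astype(float)
        X["age_lt40"] = lt40
        X["age_lt40_x_exposure"] = lt40 * X["exposure"]

    if spec.outcome == "ordinal_0_10":
        X = X.drop(columns="const")
    return X


def fit_design(
    X: pd.DataFrame, y: np.ndarray, spec: DesignSpec
) -> RegressionResult:
    """Dispatch to the model family implied by the outcome type."""
    if spec.outcome == "binary":
        return fit_logistic(X, y)
    if spec.outcome == "ordinal_0_10":
        return fit_ordinal_logistic(X, y)
    return fit_linear(X, y)


# ---------------------------------------------------------------------------
# outcomes from admission intervals

READMISSION_WINDOW_DAYS = 365  # "12 months", boundary inclusive


def merge_intervals(
    intervals: Sequence[tuple[dt.date, dt.date]], patient_id: str = ""
) -> list[tuple[dt.date, dt.date]]:
    """Sort and merge overlapping admission intervals (with a warning)."""
    ordered = sorted(intervals)
    merged: list[tuple[dt.date, dt.date]] = []
    for admit, discharge in ordered:
        if merged and admit <= merged[-1][1]:
            warnings.warn(
                f"patient {patient_id!r}: overlapping admission intervals merged",
                stacklevel=2,
            )
            merged[-1] = (merged[-1][0], max(merged[-1][1], discharge))
        else:
            merged.append((admit, discharge))
    return merged


def outcome_builder(
    records: Sequence[PatientRecord],
    window: tuple[dt.date, dt.date] = (dt.date(2011, 1, 1), dt.date(2011, 12, 31)),
) -> pd.DataFrame:
    """Per-patient outcomes derived from admission intervals.

    - ``admitted_in_window``: any admission starting inside the window;
    - ``readmitted_within_365d``: a new admission within 365 days (inclusive)
      after a discharge occurring inside the window (NaN when no in-window
      discharge exists);
    - ``first_admission_length_days``: discharge - admit, in days, for the
      first admission starting in the window (NaN when none).
    """
    start, end = window
    rows = []
    for r in records:
        adm = merge_intervals(r.admissions, r.patient_id)
        admitted = any(start <= a <= end for a, _ in adm)
        length = np.nan
        for a, d in adm:
            if start <= a <= end:
                length = float((d - a).days)
                break
        readmitted: float = np.nan
        discharges = [d for _, d in adm if start <= d <= end]
        if discharges:
            readmitted = 0.0
            for d in discharges:
                if any(0 < (a - d).days <= READMISSION_WINDOW_DAYS for a, _ in adm):
                    readmitted = 1.0
                    break
        rows.append(
            {
                "patient_id": r.patient_id,
                "admitted_in_window": float(admitted),
                "readmitted_within_365d": readmitted,
                "first_admission_length_days": length,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


def select_nearest(
    observations: Sequence[tuple[dt.date, object]], index_date: dt.date
) -> object:
    """The observation closest in time to *index_date*; ties go to the earlier one."""
    if not observations:
        raise EpiError("no observations to select from")
    return min(
        observations, key=lambda od: (abs((od[0] - index_date).days), od[0])
    )[1]
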