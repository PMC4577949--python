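"""Composite negative-symptom scale: 0-10 sum score and internal consistency.

Ten binary symptom items per patient are summed, with equal weight, into a
0-10 score; a threshold of >=2 documented symptoms dichotomises the scale.
Cronbach's alpha (sample-variance form, denominator n-1) quantifies the
intercorrelation of the ten items over a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import SYMPTOMS

DEFAULT_THRESHOLD = 2
SCORE_BANDS = ("0", "1", "2", "3", "4", "5", "6+")


@dataclass(frozen=True)
class CompositeScore:
    patient_id: str
    score: int
    above_threshold: bool


def composite_score(
    flags: Mapping[str, bool],
    threshold: int = DEFAULT_THRESHOLD,
    patient_id: str = "",
) -> CompositeScore:
    """Sum the ten binary items; dichotomise at *threshold* (default >=2)."""
    if not (0 <= threshold <= 10):
        raise ValueError(f"threshold {threshold} outside 0-10")
    missing = set(SYMPTOMS) - set(flags)
    if missing:
        raise ValueError(f"incomplete flags, missing {sorted(missing)}")
    score = sum(bool(flags[s]) for s in SYMPTOMS)
    return CompositeScore(
        patient_id=patient_id, score=score, above_threshold=score >= threshold
    )


def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha of a patients x items matrix.

    alpha = k/(k-1) * (1 - sum(var_i) / var_total), with sample variances
    (denominator n-1). May be negative; always <= 1 for non-degenerate input.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 rows and >=2 columns")
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        raise ValueError("total score has zero variance; alpha undefined")
    k = X.shape[1]
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def score_distribution(scores: Sequence[CompositeScore]) -> pd.DataFrame:
    """Counts and percentages by score band {0,1,2,3,4,5,6+} plus >=2 prevalence.

    Returns a DataFrame indexed by band with columns ``count`` and ``pct``;
    the ``attrs`` dict carries ``prevalence_ge2_pct`` and ``n``.
    """
    if not scores:
        raise ValueError("empty cohort")
    n = len(scores)
    counts = {band: 0 for band in SCORE_BANDS}
    for s in scores:
        counts["6+" if s.score >= 6 else str(s.score)] += 1
    table = pd.DataFrame(
        {
            "count": [counts[b] for b in SCORE_BANDS],
            "pct": [100.0 * counts[b] / n for b in SCORE_BANDS],
        },
        index=pd.Index(SCORE_BANDS, name="score_band"),
    )
    table.attrs["n"] = n
    table.attrs["prevalence_ge2_pct"] = float(
        table["pct"].iloc[2:].sum()
    )
    return table


def flags_to_item_matrix(
    flags_by_patient: Mapping[str, Mapping[str, bool]]
) -> pd.DataFrame:
    """Stack per-patient flag dicts into a patients x 10 binary DataFrame."""
    rows = {
        pid: [int(bool(f[s])) for s in SYMPTOMS]
        for pid, f in flags_by_patient.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(SYMPTOMS))
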