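"""Extractor evaluation: stratified k-fold cross-validation, precision/recall
per symptom, and inter-annotator agreement (percent agreement + Cohen's kappa).

The evaluation unit is the mention instance. Confusion counts are pooled
over folds (micro-average) before computing metrics — stable for rare
symptoms — with per-fold macro averages reported as secondary columns.
Metrics with a zero denominator are reported as undefined (NaN), never as
0 or 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .corpus import SYMPTOMS, AnnotationSpan, Document
from .extractor import (
    FORCED_NOT_POSITIVE,
    NOT_POSITIVE,
    POSITIVE,
    Mention,
    apply_rules,
    classify_mention,
    featurize,
    find_candidates,
)
from .lexicon import Lexicon, RuleSet
from .svm import LinearModel, TrainingError, train_classifier


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass(frozen=True)
class AgreementResult:
    percent_agreement: float
    kappa: float
    n_instances: int


def kfold_split(
    labels: Sequence[Hashable], k: int = 5, seed: int = 0
) -> list[np.ndarray]:
    """Stratified k-fold index partition, deterministic given *seed*.

    Fold sizes differ by at most one and per-fold class proportions are
    within one instance of the overall proportions.
    """
    n = len(labels)
    if n < k:
        raise ValueError(f"cannot split {n} instances into {k} folds")
    counts = Counter(labels)
    small = {lab: c for lab, c in counts.items() if c < k}
    if small:
        raise ValueError(f"classes smaller than k={k} under stratification: {small}")
    y = np.asarray([str(lab) for lab in labels])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(n), y)]


def precision_recall(
    predictions: Mapping[Hashable, str],
    gold: Mapping[Hashable, str],
    symptom_of: Mapping[Hashable, str],
) -> pd.DataFrame:
    """Per-symptom precision/recall from aligned prediction and gold labels.

    Keys of *predictions* and *gold* must coincide exactly; labels are
    ``positive`` / ``not_positive``.
    """
    if set(predictions) != set(gold):
        raise ValueError("predictions and gold are not aligned on the same instances")
    per_symptom = {s: ConfusionCounts() for s in SYMPTOMS}
    for key, pred in predictions.items():
        g = gold[key]
        s = symptom_of[key]
        cell = ConfusionCounts(
            tp=int(pred == POSITIVE and g == POSITIVE),
            fp=int(pred == POSITIVE and g == NOT_POSITIVE),
            fn=int(pred == NOT_POSITIVE and g == POSITIVE),
            tn=int(pred == NOT_POSITIVE and g == NOT_POSITIVE),
        )
        per_symptom[s] = per_symptom[s] + cell
    rows = []
    for s in SYMPTOMS:
        c = per_symptom[s]
        rows.append(
            {"symptom": s, "precision": c.precision, "recall": c.recall,
             "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn, "n": c.n}
        )
    return pd.DataFrame(rows)


def label_mentions(
    documents: Sequence[Document],
    gold_spans: Sequence[AnnotationSpan],
    lexicon: Lexicon,
) -> list[tuple[Mention, str]]:
    """Pair extracted candidate mentions with gold labels.

    A mention is gold-positive iff it overlaps an *affirmed* gold span of the
    same symptom in the same document; negated and irrelevant gold spans (and
    unannotated cue matches) are gold not-positive.
    """
    affirmed: dict[str, list[tuple[int, int, str]]] = {}
    for span in gold_spans:
        if span.polarity == "affirmed":
            affirmed.setdefault(span.doc_id, []).append(
                (span.start, span.end, span.symptom)
            )
    labelled: list[tuple[Mention, str]] = []
    for doc in documents:
        for mention in find_candidates(doc, lexicon):
            hit = any(
                s == mention.symptom and mention.cue_start < e and start < mention.cue_end
                for start, e, s in affirmed.get(doc.doc_id, [])
            )
            labelled.append((mention, POSITIVE if hit else NOT_POSITIVE))
    return labelled


def _constant_model(label: str) -> LinearModel:
    """Bias-only model for folds where the rules absorb one class entirely."""
    return LinearModel(
        vocabulary={}, weights=np.zeros(0),
        bias=1.0 if label == POSITIVE else -1.0,
        hyperparams={"constant": label},
    )


def _train_fold(
    train: Sequence[tuple[Mention, str]],
    rules: RuleSet,
    C: float,
    seed: int,
    include_symptom: bool,
) -> LinearModel:
    # rule-forced mentions are excluded: rules pre-empt them at inference
    examples = [
        (featurize(m, include_symptom=include_symptom), lab)
        for m, lab in train
        if apply_rules(m, rules) != FORCED_NOT_POSITIVE
    ]
    try:
        return train_classifier(examples, C=C, seed=seed)
    except TrainingError:
        labels = {lab for _, lab in examples} or {NOT_POSITIVE}
        return _constant_model(next(iter(labels)))


def cross_validate(
    labelled: Sequence[tuple[Mention, str]],
    k: int = 5,
    seed: int = 13,
    rules: RuleSet | None = None,
    C: float = 1.0,
    per_symptom: bool = True,
) -> pd.DataFrame:
    """Stratified k-fold CV of the full hybrid (rules + model) per symptom.

    Each held-out fold is predicted by a model trained on the remaining
    folds; confusion counts are pooled over folds before computing the
    precision/recall columns. ``per_symptom=False`` trains one shared model
    with the symptom label as a categorical feature.
    """
    rules = rules or RuleSet()
    pooled = {s: ConfusionCounts() for s in SYMPTOMS}
    fold_metrics: dict[str, list[tuple[float, float]]] = {s: [] for s in SYMPTOMS}

    groups: dict[str, list[tuple[Mention, str]]]
    if per_symptom:
        groups = {s: [] for s in SYMPTOMS}
        for m, lab in labelled:
            groups[m.symptom].append((m, lab))
        groups = {s: g for s, g in groups.items() if g}
    else:
        groups = {"__all__": list(labelled)}

    for _, instances in sorted(groups.items()):
        folds = kfold_split([lab for _, lab in instances], k=k, seed=seed)
        for test_idx in folds:
            test_set = set(test_idx.tolist())
            train = [inst for i, inst in enumerate(instances) if i not in test_set]
            test = [instances[i] for i in test_idx]
            model = _train_fold(train, rules, C, seed, include_symptom=not per_symptom)
            fold_counts = {s: ConfusionCounts() for s in SYMPTOMS}
            for m, gold_label in test:
                pred = classify_mention(m, model, rules)
                cell = ConfusionCounts(
                    tp=int(pred == POSITIVE and gold_label == POSITIVE),
                    fp=int(pred == POSITIVE and gold_label == NOT_POSITIVE),
                    fn=int(pred == NOT_POSITIVE and gold_label == POSITIVE),
                    tn=int(pred == NOT_POSITIVE and gold_label == NOT_POSITIVE),
                )
                pooled[m.symptom] = pooled[m.symptom] + cell
                fold_counts[m.symptom] = fold_counts[m.symptom] + cell
            for s, c in fold_counts.items():
                if c.n:
                    fold_metrics[s].append((c.precision, c.recall))

    rows = []
    for s in SYMPTOMS:
        c = pooled[s]
        if c.n == 0:
            continue
        macro = np.array(fold_metrics[s], dtype=float)
        rows.append(
            {
                "symptom": s,
                "precision": c.precision,
                "recall": c.recall,
                "precision_macro": float(np.nanmean(macro[:, 0])) if macro.size else float("nan"),
                "recall_macro": float(np.nanmean(macro[:, 1])) if macro.size else float("nan"),
                "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn, "n": c.n,
            }
        )
    return pd.DataFrame(rows)


def agreement(
    ann_a: Sequence[Hashable], ann_b: Sequence[Hashable]
) -> AgreementResult:
    """Percent agreement and Cohen's kappa between two annotators.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    marginal label frequencies of each annotator.
    """
    if len(ann_a) != len(ann_b):
        raise ValueError("annotators labelled different numbers of instances")
    n = len(ann_a)
    if n == 0:
        raise ValueError("no instances")
    p_o = sum(a == b for a, b in zip(ann_a, ann_b)) / n
    ca, cb = Counter(ann_a), Counter(ann_b)
    labels = set(ca) | set(cb)
    p_e = sum((ca[lab] / n) * (cb[lab] / n) for lab in labels)
    if p_e == 1.0:
        raise ValueError("both annotators constant and identical; kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(
        percent_agreement=100.0 * p_o, kappa=kappa, n_instances=n
    )
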