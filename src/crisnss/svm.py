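"""Deterministic L2-regularised hinge-loss (linear SVM) trainer.

Minimises

    P(w) = 0.5 * ||w||^2  +  C * sum_i max(0, 1 - y_i * w . x_i)

over sparse binary (or real-valued) feature vectors, with the intercept
included as a constant-1 feature (and therefore regularised — a standard
simplification that changes nothing materially at these feature scales).
The optimiser is cyclic dual coordinate descent on the box-constrained dual;
example order is normalised by a stable sort before training, so the fitted
weights are identical regardless of input order. The duality gap gives a
certified bound on suboptimality: gap g implies ||w - w*|| <= sqrt(2 g).

The trained model is a plain vocabulary -> weight mapping serialisable to
JSON; tokens unseen at prediction time simply contribute nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class TrainingError(ValueError):
    """Degenerate training data (e.g. a single class)."""


@dataclass
class LinearModel:
    """A linear decision function over named sparse features."""

    vocabulary: dict[str, int]
    weights: np.ndarray  # aligned to vocabulary, length == len(vocabulary)
    bias: float
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.vocabulary),):
            raise ValueError("weight vector length must equal vocabulary size")

    def decision_value(self, features: Iterable[str]) -> float:
        """w . x + b for a set of binary named features; unseen names ignored."""
        total = self.bias
        seen = set()
        for name in features:
            idx = self.vocabulary.get(name)
            if idx is not None and name not in seen:
                total += self.weights[idx]
                seen.add(name)
        return float(total)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "vocabulary": self.vocabulary,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "hyperparams": self.hyperparams,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            vocabulary=payload["vocabulary"],
            weights=np.array(payload["weights"], dtype=float),
            bias=float(payload["bias"]),
            hyperparams=payload.get("hyperparams", {}),
        )


def svm_objective(
    X: Sequence[Sequence[int]],
    values: Sequence[Sequence[float]] | None,
    y: np.ndarray,
    w: np.ndarray,
    C: float,
) -> float:
    """Primal hinge-loss objective at *w* (bias column included in *X*)."""
    margins = np.array([_dot(w, idx, None if values is None else values[i])
                        for i, idx in enumerate(X)])
    hinge = np.maximum(0.0, 1.0 - y * margins)
    return 0.5 * float(w @ w) + C * float(hinge.sum())


def _dot(w: np.ndarray, idx: Sequence[int], vals: Sequence[float] | None) -> float:
    if vals is None:
        return float(w[list(idx)].sum())
    return float(sum(w[j] * v for j, v in zip(idx, vals)))


def fit_linear_svm(
    X: Sequence[Sequence[int]],
    y: Sequence[int],
    n_features: int,
    C: float = 1.0,
    values: Sequence[Sequence[float]] | None = None,
    gap_tol: float = 1e-12,
    max_sweeps: int = 100_000,
) -> np.ndarray:
    """Fit w (length *n_features*) by cyclic dual coordinate descent.

    *X* holds per-example feature index lists; *values* optional matching
    feature values (default binary 1.0). *y* in {-1, +1}. The caller is
    responsible for appending a bias column if an intercept is wanted.
    Stops when the duality gap falls below ``gap_tol * max(1, |P|)``.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise TrainingError("labels must be -1/+1")
    if len(set(y.tolist())) < 2:
        raise TrainingError("training set contains a single class")
    n = len(X)
    idx_arrays = [np.asarray(ix, dtype=np.intp) for ix in X]
    val_arrays = (
        [np.ones(len(ix)) for ix in idx_arrays]
        if values is None
        else [np.asarray(v, dtype=float) for v in values]
    )
    qii = np.array([float(v @ v) for v in val_arrays])
    w = np.zeros(n_features)
    alpha = np.zeros(n)
    order = range(n)
    for _ in range(max_sweeps):
        for i in order:
            if qii[i] == 0.0:
                continue
            g = y[i] * float(w[idx_arrays[i]] @ val_arrays[i]) - 1.0
            a_new = min(max(alpha[i] - g / qii[i], 0.0), C)
            delta = a_new - alpha[i]
            if delta != 0.0:
                w[idx_arrays[i]] += delta * y[i] * val_arrays[i]
                alpha[i] = a_new
        primal = svm_objective(X, values, y, w, C)
        dual = float(alpha.sum()) - 0.5 * float(w @ w)
        if primal - dual <= gap_tol * max(1.0, abs(primal)):
            break
    return w


def train_classifier(
    examples: Sequence[tuple[frozenset[str] | set[str], str]],
    C: float = 1.0,
    seed: int = 0,
    gap_tol: float = 1e-12,
) -> LinearModel:
    """Train a :class:`LinearModel` from (feature-name set, label) pairs.

    Labels are ``"positive"`` / ``"not_positive"``. Examples are sorted by a
    stable key before optimisation, so shuffled input yields identical
    weights. The intercept is learned as a constant feature.
    """
    if not examples:
        raise TrainingError("no training examples")
    labels = {lab for _, lab in examples}
    if labels - {"positive", "not_positive"}:
        raise TrainingError(f"unknown labels {labels}")
    if len(labels) < 2:
        raise TrainingError("training set contains a single class")

    normalised = sorted(
        ((tuple(sorted(feats)), lab) for feats, lab in examples),
        key=lambda e: (e[1], e[0]),
    )
    vocab: dict[str, int] = {}
    for feats, _ in normalised:
        for name in feats:
            if name not in vocab:
                vocab[name] = len(vocab)
    vocab = {name: i for i, name in enumerate(sorted(vocab))}
    n_feat = len(vocab)
    bias_col = n_feat
    X = [[vocab[f] for f in feats] + [bias_col] for feats, _ in normalised]
    y = [1 if lab == "positive" else -1 for _, lab in normalised]
    w = fit_linear_svm(X, y, n_feat + 1, C=C, gap_tol=gap_tol)
    return LinearModel(
        vocabulary=vocab,
        weights=w[:n_feat],
        bias=float(w[bias_col]),
        hyperparams={"C": C, "ngram_orders": [1, 2], "seed": seed},
    )
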