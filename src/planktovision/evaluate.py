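"""Confusion matrices, recall/precision/F-measure, and CV drivers.

Per class: recall R = TP / (actual positives), precision P = TP /
(predicted positives), error rate 1−P, and F = 2PR/(P+R) (0 when P+R=0).
Headline numbers are macro averages (unweighted class means); micro
averages (pooled counts — for recall this equals overall accuracy) are
also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = ["ConfusionMatrix", "Metrics", "confusion_matrix", "metrics", "cross_validate"]


@dataclass
class ConfusionMatrix:
    """C×C counts: rows are actual classes, columns predicted classes."""

    counts: np.ndarray
    classes: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("class rosters differ")
        return ConfusionMatrix(self.counts + other.counts, self.classes)


def confusion_matrix(
    actual: Sequence, predicted: Sequence, classes: Sequence[str] | None = None
) -> ConfusionMatrix:
    """Count (actual, predicted) pairs over a shared class roster."""
    actual = list(actual)
    predicted = list(predicted)
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    roster = sorted(set(actual) | set(predicted)) if classes is None else list(classes)
    index = {c: i for i, c in enumerate(roster)}
    counts = np.zeros((len(roster), len(roster)), dtype=np.int64)
    for a, p in zip(actual, predicted):
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(counts, roster)


@dataclass
class Metrics:
    """Per-class and averaged recall, precision, error rate and F-measure."""

    classes: list[str]
    recall: np.ndarray
    precision: np.ndarray
    f_measure: np.ndarray
    macro_recall: float
    macro_precision: float
    macro_f: float
    micro_recall: float
    micro_precision: float

    @property
    def macro_error(self) -> float:
        """The paper-style error rate, 1 − precision (macro)."""
        return 1.0 - self.macro_precision

    def as_dict(self) -> dict:
        return {
            "macro_recall": self.macro_recall,
            "macro_precision": self.macro_precision,
            "macro_error": self.macro_error,
            "macro_f": self.macro_f,
            "micro_recall": self.micro_recall,
            "micro_precision": self.micro_precision,
        }


def metrics(cm: ConfusionMatrix) -> Metrics:
    """Derive the evaluation measures from a confusion matrix."""
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    actual = counts.sum(axis=1)
    predicted = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(actual > 0, tp / np.maximum(actual, 1e-300), 0.0)
        precision = np.where(predicted > 0, tp / np.maximum(predicted, 1e-300), 0.0)
    pr = precision + recall
    f = np.where(pr > 0, 2.0 * precision * recall / np.maximum(pr, 1e-300), 0.0)
    return Metrics(
        classes=list(cm.classes),
        recall=recall,
        precision=precision,
        f_measure=f,
        macro_recall=float(recall.mean()),
        macro_precision=float(precision.mean()),
        macro_f=float(f.mean()),
        micro_recall=float(tp.sum() / max(counts.sum(), 1.0)),
        micro_precision=float(tp.sum() / max(counts.sum(), 1.0)),
    )


@dataclass
class CVResult:
    fold_metrics: list[Metrics]
    fold_confusions: list[ConfusionMatrix]
    pooled_confusion: ConfusionMatrix
    pooled_metrics: Metrics = field(init=False)

    def __post_init__(self) -> None:
        self.pooled_metrics = metrics(self.pooled_confusion)


def cross_validate(
    labels: Sequence[str],
    fit_predict: Callable[[np.ndarray, np.ndarray], Sequence[str]],
    protocol: str = "k-fold",
    k: int = 2,
    seed: int = 0,
) -> CVResult:
    """Stratified evaluation driver.

    ``fit_predict(train_idx, test_idx)`` must fit every data-dependent
    stage (feature selection, codebook, shape templates, classifier) on the
    training indices only and return predictions for the test indices.
    ``protocol`` is ``"k-fold"`` (each fold tested once) or ``"holdout"``
    (a single stratified 50/50 split, the second half tested).
    """
    y = np.asarray(list(labels))
    classes, counts = np.unique(y, return_counts=True)
    if protocol == "k-fold":
        if counts.min() < k:
            small = classes[counts.argmin()]
            raise ValueError(f"class {small!r} has fewer than k={k} samples")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = [(tr, te) for tr, te in splitter.split(np.zeros(len(y)), y)]
    elif protocol == "holdout":
        tr, te = train_test_split(
            np.arange(len(y)), test_size=0.5, stratify=y, random_state=seed
        )
        splits = [(np.sort(tr), np.sort(te))]
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    roster = sorted(classes.tolist())
    fold_cms, fold_ms = [], []
    for tr, te in splits:
        pred = list(fit_predict(tr, te))
        cm = confusion_matrix(y[te].tolist(), pred, classes=roster)
        fold_cms.append(cm)
        fold_ms.append(metrics(cm))
    pooled = fold_cms[0]
    for cm in fold_cms[1:]:
        pooled = pooled + cm
    return CVResult(fold_metrics=fold_ms, fold_confusions=fold_cms, pooled_confusion=pooled)
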