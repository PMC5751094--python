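"""Per-group wrapper feature selection (sequential forward search).

Each of the ten feature groups is reduced independently: starting from the
empty set, the feature whose addition maximizes the stratified k-fold
cross-validated accuracy of a linear SVM evaluator is added greedily; the
search stops after three consecutive non-improving additions or at the
dimension cap, and the best-scoring subset seen is retained.  For
high-dimensional groups the candidate pool is pre-ranked by a one-way
ANOVA F-score and truncated, which bounds the quadratic wrapper cost.

Selection sees only training data; features are z-scored with training
statistics before evaluation (the SVM is scale sensitive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_selection import f_classif
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import LinearSVC

__all__ = ["FeatureGroupSet", "SelectionResult", "wrapper_select", "select_all_groups", "apply_selection"]


@dataclass
class FeatureGroupSet:
    """Per-sample feature tables partitioned into named groups.

    All groups share the sample ordering; ``labels`` (optional) has one
    entry per sample.
    """

    groups: dict[str, np.ndarray]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        ns = {g: t.shape[0] for g, t in self.groups.items()}
        if len(set(ns.values())) > 1:
            raise ValueError(f"groups disagree on sample count: {ns}")
        if self.labels is not None and self.groups:
            n = next(iter(ns.values()))
            if len(self.labels) != n:
                raise ValueError("labels length does not match sample count")

    @property
    def n_samples(self) -> int:
        return next(iter(self.groups.values())).shape[0] if self.groups else 0

    def subset(self, idx: np.ndarray) -> "FeatureGroupSet":
        labels = [self.labels[i] for i in idx] if self.labels is not None else None
        return FeatureGroupSet(
            groups={g: t[idx] for g, t in self.groups.items()}, labels=labels
        )

    def concatenated(self) -> np.ndarray:
        return np.hstack([self.groups[g] for g in sorted(self.groups)])


@dataclass
class SelectionResult:
    """Retained column indices per group, with the CV score trace."""

    indices: dict[str, np.ndarray]
    score_trace: dict[str, list[float]] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {g: np.asarray(ix).tolist() for g, ix in self.indices.items()}


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, folds: int, seed: int
) -> float:
    clf = LinearSVC(C=1.0, dual="auto", max_iter=5000)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return float(cross_val_score(clf, X, y, cv=cv, scoring="accuracy").mean())


def wrapper_select(
    group_table: np.ndarray,
    labels,
    folds: int = 3,
    seed: int = 0,
    max_features: int = 20,
    candidate_cap: int = 60,
    patience: int = 3,
) -> SelectionResult:
    """Greedy forward selection on one group's feature table.

    Returns the retained column indices (into the original table) plus the
    CV-accuracy trace.  Deterministic given the seed: folds are seeded and
    score ties break on the lower candidate rank.
    """
    X = np.asarray(group_table, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("expected a 2-D sample×feature table")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("wrapper selection needs at least 2 classes")
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` samples")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Xz = (X - mu) / np.where(sd > 0, sd, 1.0)
    d = Xz.shape[1]

    if d == 1:
        score = _cv_accuracy(Xz, y, folds, seed)
        return SelectionResult({"group": np.array([0])}, {"group": [score]})

    # pre-rank candidates by ANOVA F-score, keep the strongest
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns are legitimately scored 0
        f_scores, _ = f_classif(Xz, y)
    f_scores = np.nan_to_num(f_scores, nan=0.0, posinf=0.0)
    order = np.argsort(-f_scores, kind="stable")
    candidates = list(order[: min(candidate_cap, d)])

    selected: list[int] = []
    trace: list[float] = []
    best_score = -np.inf
    best_subset: list[int] = []
    stall = 0
    while candidates and len(selected) < max_features and stall < patience:
        step_best, step_feat = -np.inf, None
        for feat in candidates:
            sc = _cv_accuracy(Xz[:, selected + [feat]], y, folds, seed)
            if sc > step_best:
                step_best, step_feat = sc, feat
        selected.append(step_feat)
        candidates.remove(step_feat)
        trace.append(step_best)
        if step_best > best_score + 1e-12:
            best_score = step_best
            best_subset = list(selected)
            stall = 0
        else:
            stall += 1
    retained = np.array(sorted(best_subset), dtype=int)
    return SelectionResult({"group": retained}, {"group": trace})


def select_all_groups(
    groups: FeatureGroupSet,
    labels,
    folds: int = 3,
    seed: int = 0,
    **kwargs,
) -> SelectionResult:
    """Run :func:`wrapper_select` independently on every group."""
    indices: dict[str, np.ndarray] = {}
    traces: dict[str, list[float]] = {}
    for name in sorted(groups.groups):
        table = groups.groups[name]
        if table.shape[1] == 0:
            raise ValueError(f"group {name!r} has no columns")
        res = wrapper_select(table, labels, folds=folds, seed=seed, **kwargs)
        indices[name] = res.indices["group"]
        traces[name] = res.score_trace["group"]
    return SelectionResult(indices, traces)


def apply_selection(groups: FeatureGroupSet, result: SelectionResult) -> FeatureGroupSet:
    """Reduce every group to its retained columns (sample order unchanged)."""
    out = {}
    for name, table in groups.groups.items():
        if name not in result.indices:
            raise KeyError(f"selection result lacks group {name!r}")
        idx = np.asarray(result.indices[name], dtype=int)
        if idx.size == 0:
            raise ValueError(f"selection for group {name!r} is empty")
        if idx.min() < 0 or idx.max() >= table.shape[1]:
            raise IndexError(
                f"selection index out of bounds for group {name!r} "
                f"(dim {table.shape[1]})"
            )
        out[name] = table[:, idx]
    return FeatureGroupSet(groups=out, labels=groups.labels)
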