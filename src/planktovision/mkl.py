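"""Nonlinear multiple kernel learning (NLMKL) over per-group base kernels.

One base kernel is computed per (feature group, kernel family) pair, the
families being linear, polynomial (degree 3) and Gaussian (median-distance
width).  The combined kernel is the bounded-degree polynomial expansion

    K_η = Σ_{k_1+⋯+k_p = d}  η_1^{k_1} ⋯ η_p^{k_p} · K_1^{k_1} ∘ ⋯ ∘ K_p^{k_p}

with entrywise (Schur) kernel products, nonnegative weights η and the norm
constraint ‖η‖₂ ≤ Λ.  By the Schur product theorem the combination stays
positive semidefinite.

Training alternates, per one-vs-rest binary problem:

(a) with η fixed, solve the soft-margin SVM dual on K_η for the dual
    coefficients α (box [0, C]);
(b) with α fixed, take a projected gradient step on η that *descends* the
    optimal-value dual objective J*(η) = max_α [Σα − ½ (αy)ᵀ K_η (αy)] —
    the margin-maximizing direction (J* is differentiable in η at the dual
    optimum with ∂J*/∂η_m = −½ (αy)ᵀ ∂K_η/∂η_m (αy)); the step is
    backtracked until J*(η_new) does not increase, so the recorded
    objective trace is nonincreasing.

Kernels are trace-normalized before combination so no feature group
dominates η through scale alone.  The decision function is
f(x) = Σ_i α_i y_i K_η(x_i, x) + b, and multiclass prediction is
one-vs-rest argmax with ties broken toward the lowest class index.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from planktovision.selection import FeatureGroupSet

__all__ = [
    "KernelSpec",
    "compute_kernel",
    "nlmkl_combine",
    "MKLModel",
    "train_nlmkl",
    "train_svm_single",
    "predict",
    "decision_values",
]

FAMILIES = ("linear", "polynomial", "gaussian")


@dataclass
class KernelSpec:
    """One base kernel: family, resolved parameters, source feature group."""

    family: str
    group: str = "all"
    degree: int = 3          # polynomial
    scale: float | None = None   # polynomial inner-product scale (1/d if None)
    width: float | None = None   # gaussian; median-distance heuristic if None
    trace_factor: float = 1.0    # divisor recorded at training time

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        if self.width is not None and self.width <= 0:
            raise ValueError("gaussian width must be > 0")


def median_distance(X: np.ndarray) -> float:
    """Median nonzero pairwise Euclidean distance (Gaussian width heuristic)."""
    X = np.asarray(X, dtype=float)
    sq = (X**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0)
    vals = np.sqrt(d2[np.triu_indices_from(d2, k=1)])
    vals = vals[vals > 0]
    return float(np.median(vals)) if vals.size else 1.0


def compute_kernel(X: np.ndarray, Z: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Evaluate the base kernel between the rows of X and Z (raw, unnormalized)."""
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if X.shape[1] != Z.shape[1]:
        raise ValueError(f"feature dimension mismatch: {X.shape[1]} vs {Z.shape[1]}")
    if spec.family == "linear":
        return X @ Z.T
    if spec.family == "polynomial":
        s = spec.scale if spec.scale is not None else 1.0 / max(X.shape[1], 1)
        return (s * (X @ Z.T) + 1.0) ** spec.degree
    w = spec.width if spec.width is not None else median_distance(X)
    sqx = (X**2).sum(axis=1)[:, None]
    sqz = (Z**2).sum(axis=1)[None, :]
    d2 = np.maximum(sqx + sqz - 2.0 * X @ Z.T, 0.0)
    return np.exp(-d2 / (2.0 * w**2))


def _combine_fast_d2(bases: Sequence[np.ndarray], eta: np.ndarray) -> np.ndarray:
    S = sum(e * K for e, K in zip(eta, bases))
    out = S * S
    for e, K in zip(eta, bases):
        out += (e * K) * (e * K)
    return 0.5 * out


def nlmkl_combine(
    bases: Sequence[np.ndarray], eta: np.ndarray, degree: int = 2
) -> np.ndarray:
    """Degree-d polynomial kernel combination (sum over all multi-indices).

    Multi-indices carry no multinomial coefficients: the combination is
    Σ_{|k|=d} Πη^k ΠK^k with entrywise matrix products.
    """
    eta = np.asarray(eta, dtype=float)
    if np.any(eta < 0):
        raise ValueError("combination weights must be nonnegative")
    if degree < 1:
        raise ValueError("combination degree must be >= 1")
    if len(bases) != eta.size:
        raise ValueError("one weight per base kernel required")
    shapes = {K.shape for K in bases}
    if len(shapes) > 1:
        raise ValueError("base kernels must share their shape")
    if degree == 1:
        return sum(e * K for e, K in zip(eta, bases))
    if degree == 2:
        return _combine_fast_d2(bases, eta)
    out = np.zeros_like(np.asarray(bases[0], dtype=float))
    for combo in itertools.combinations_with_replacement(range(len(bases)), degree):
        term = np.ones_like(out)
        coeff = 1.0
        for m in combo:
            coeff *= eta[m]
            term = term * bases[m]
        out += coeff * term
    return out


def _grad_quadform(
    bases: Sequence[np.ndarray], eta: np.ndarray, degree: int, beta: np.ndarray
) -> np.ndarray:
    """g_m = βᵀ (∂K_η/∂η_m) β for every base kernel m."""
    p = len(bases)
    B = np.outer(beta, beta)
    if degree == 1:
        return np.array([float((B * K).sum()) for K in bases])
    if degree == 2:
        S = sum(e * K for e, K in zip(eta, bases))
        BS = B * S
        return np.array(
            [
                float((BS * K).sum()) + eta[m] * float((B * K * K).sum())
                for m, K in enumerate(bases)
            ]
        )
    g = np.zeros(p)
    for combo in itertools.combinations_with_replacement(range(p), degree):
        term = np.ones_like(bases[0])
        for m in combo:
            term = term * bases[m]
        quad = float((B * term).sum())
        counts = np.bincount(np.array(combo), minlength=p)
        # coefficient derivative: d/dη_m Π η^k = k_m η_m^{k_m-1} Π_{m'≠m} η^{k_m'}
        for m in np.flatnonzero(counts):
            c = counts[m] * eta[m] ** (counts[m] - 1)
            for mm in np.flatnonzero(counts):
                if mm != m:
                    c *= eta[mm] ** counts[mm]
            g[m] += c * quad
    return g


def _project(eta: np.ndarray, lam: float) -> np.ndarray:
    eta = np.maximum(eta, 0.0)
    nrm = np.linalg.norm(eta)
    if nrm > lam:
        eta = eta * (lam / nrm)
    return eta


def _solve_svm(K: np.ndarray, y: np.ndarray, C: float):
    """Soft-margin SVM dual on a precomputed kernel.

    Returns (beta, b, objective) where beta_i = α_i y_i and
    objective = Σα − ½ βᵀKβ.
    """
    svc = SVC(C=C, kernel="precomputed", tol=1e-8)
    svc.fit(K, y)
    beta = np.zeros(K.shape[0])
    beta[svc.support_] = svc.dual_coef_[0]
    alpha = np.abs(beta)
    obj = float(alpha.sum() - 0.5 * beta @ K @ beta)
    return beta, float(svc.intercept_[0]), obj


@dataclass
class BinaryProblem:
    positive_class: str
    eta: np.ndarray
    beta: np.ndarray
    bias: float
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True


@dataclass
class MKLModel:
    """A trained (possibly degenerate single-kernel) MKL classifier."""

    specs: list[KernelSpec]
    degree: int
    lam: float
    C: float
    classes: list[str]
    problems: list[BinaryProblem]
    train_groups: dict[str, np.ndarray]       # z-scored training features
    scalers: dict[str, tuple[np.ndarray, np.ndarray]]
    seed: int = 0
    metadata: dict = field(default_factory=dict)


def _prepare_groups(
    groups: FeatureGroupSet, scalers: dict | None = None
) -> tuple[dict[str, np.ndarray], dict]:
    """Z-score each group's table; reuse training statistics when given."""
    out, sc = {}, {}
    for name in sorted(groups.groups):
        X = np.asarray(groups.groups[name], dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError(f"non-finite features in group {name!r}")
        if scalers is None:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            mu, sd = scalers[name]
        out[name] = (X - mu) / sd
        sc[name] = (mu, sd)
    return out, sc


def _base_kernels_train(
    tables: dict[str, np.ndarray], families: Sequence[str]
) -> tuple[list[KernelSpec], list[np.ndarray]]:
    specs, mats = [], []
    n = next(iter(tables.values())).shape[0]
    for g in sorted(tables):
        X = tables[g]
        for fam in families:
            spec = KernelSpec(family=fam, group=g)
            if fam == "gaussian":
                spec.width = median_distance(X)
            if fam == "polynomial":
                spec.scale = 1.0 / max(X.shape[1], 1)
            K = compute_kernel(X, X, spec)
            tr = float(np.trace(K))
            spec.trace_factor = tr / n if tr > 0 else 1.0
            specs.append(spec)
            mats.append(K / spec.trace_factor)
    return specs, mats


def _train_binary(
    bases: list[np.ndarray],
    y: np.ndarray,
    C: float,
    degree: int,
    lam: float,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, list[float], bool]:
    p = len(bases)
    eta = _project(np.full(p, lam / np.sqrt(p)), lam)
    K = nlmkl_combine(bases, eta, degree)
    beta, b, obj = _solve_svm(K, y, C)
    trace = [obj]
    step = 0.5
    converged = max_iter == 0
    for _ in range(max_iter):
        grad = -0.5 * _grad_quadform(bases, eta, degree, beta)
        gn = np.linalg.norm(grad)
        if gn < 1e-12:
            converged = True
            break
        accepted = False
        while step >= 1e-5:
            eta_new = _project(eta - (step / gn) * grad, lam)
            if np.allclose(eta_new, eta):
                break
            K_new = nlmkl_combine(bases, eta_new, degree)
            beta_new, b_new, obj_new = _solve_svm(K_new, y, C)
            if obj_new <= obj + 1e-9:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True
            break
        delta = obj - obj_new
        eta, beta, b, obj = eta_new, beta_new, b_new, obj_new
        trace.append(obj)
        step = min(step * 1.5, 1.0)
        if delta < tol:
            converged = True
            break
    return eta, beta, b, trace, converged


def train_nlmkl(
    groups: FeatureGroupSet,
    labels=None,
    families: Sequence[str] = FAMILIES,
    C: float = 10.0,
    degree: int = 2,
    seed: int = 0,
    lam: float = 1.0,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> MKLModel:
    """Train a one-vs-rest NLMKL classifier on the given feature groups.

    ``families`` picks the base-kernel families; with ``g`` groups there are
    ``g × len(families)`` base kernels, each trace-normalized.  A warning is
    recorded in the model metadata for binary problems that hit the
    iteration cap without meeting the objective tolerance.
    """
    y = np.asarray(labels if labels is not None else groups.labels)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for fam in families:
        if fam not in FAMILIES:
            raise ValueError(f"unknown kernel family {fam!r}")

    tables, scalers = _prepare_groups(groups)
    specs, bases = _base_kernels_train(tables, families)

    positives = classes[:1] if len(classes) == 2 else classes
    problems, warnings = [], []
    for pos in positives:
        ybin = np.where(y == pos, 1.0, -1.0)
        eta, beta, b, trace, conv = _train_binary(
            bases, ybin, C, degree, lam, max_iter, tol
        )
        if not conv:
            warnings.append(f"binary problem {pos!r} hit max_iter={max_iter}")
        problems.append(
            BinaryProblem(positive_class=pos, eta=eta, beta=beta, bias=b,
                          objective_trace=trace, converged=conv)
        )
    return MKLModel(
        specs=specs, degree=degree, lam=lam, C=C, classes=classes,
        problems=problems, train_groups=tables, scalers=scalers, seed=seed,
        metadata={"warnings": warnings, "families": list(families)},
    )


def train_svm_single(
    features: np.ndarray,
    labels,
    family: str = "gaussian",
    C: float = 10.0,
    seed: int = 0,
) -> MKLModel:
    """Plain single-kernel SVM on a concatenated feature table.

    The degenerate MKL configuration: one group, one family, η ≡ 1,
    combination degree 1, no weight optimization.
    """
    groups = FeatureGroupSet(groups={"all": np.asarray(features, dtype=float)})
    return train_nlmkl(
        groups, labels, families=[family], C=C, degree=1, seed=seed,
        lam=1.0, max_iter=0,
    )


def decision_values(model: MKLModel, groups: FeatureGroupSet) -> np.ndarray:
    """Per-problem decision values f(x), shape (n_samples, n_problems)."""
    if set(groups.groups) != set(model.train_groups):
        raise ValueError(
            f"group roster mismatch: {sorted(groups.groups)} vs "
            f"{sorted(model.train_groups)}"
        )
    tables, _ = _prepare_groups(groups, scalers=model.scalers)
    for g in tables:
        if tables[g].shape[1] != model.train_groups[g].shape[1]:
            raise ValueError(f"group {g!r} dimension differs from training")
    cross = []
    for spec in model.specs:
        K = compute_kernel(tables[spec.group], model.train_groups[spec.group], spec)
        cross.append(K / spec.trace_factor)
    out = np.empty((next(iter(tables.values())).shape[0], len(model.problems)))
    for j, prob in enumerate(model.problems):
        Kc = nlmkl_combine(cross, prob.eta, model.degree)
        out[:, j] = Kc @ prob.beta + prob.bias
    return out


def predict(model: MKLModel, groups: FeatureGroupSet) -> list[str]:
    """One-vs-rest prediction: argmax decision value, ties to lowest class."""
    dv = decision_values(model, groups)
    if len(model.classes) == 2 and dv.shape[1] == 1:
        pos = model.problems[0].positive_class
        neg = next(c for c in model.classes if c != pos)
        first = min(model.classes)
        return [
            (pos if v > 0 else neg) if v != 0 else first for v in dv[:, 0]
        ]
    order = [p.positive_class for p in model.problems]
    picks = dv.argmax(axis=1)
    return [order[i] for i in picks]
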