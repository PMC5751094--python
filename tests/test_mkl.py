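import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from planktovision import mkl as M
from planktovision.selection import FeatureGroupSet


def _two_class_groups(seed=0, n_per=20, sep=4.0):
    """Group A separates two Gaussian classes at `sep`·σ; group B is noise."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    y = np.array(["neg"] * n_per + ["pos"] * n_per)
    a = rng.normal(0, 1, (n, 3))
    a[n_per:] += sep / np.sqrt(3)
    b = rng.normal(0, 1, (n, 3))
    return FeatureGroupSet(groups={"informative": a, "noise": b}, labels=y.tolist()), y


class TestComputeKernel:
    def test_gaussian_unit_diagonal(self):
        X = np.random.default_rng(0).random((6, 4))
        K = M.compute_kernel(X, X, M.KernelSpec("gaussian", width=1.3))
        assert np.allclose(np.diag(K), 1.0)

    def test_linear_orthonormal_rows_give_identity(self):
        K = M.compute_kernel(np.eye(4), np.eye(4), M.KernelSpec("linear"))
        assert np.allclose(K, np.eye(4))

    def test_matches_scalar_formula_evaluation(self):
        rng = np.random.default_rng(1)
        X = rng.random((5, 3))
        for spec in (
            M.KernelSpec("linear"),
            M.KernelSpec("polynomial", degree=3, scale=1 / 3),
            M.KernelSpec("gaussian", width=0.8),
        ):
            K = M.compute_kernel(X, X, spec)
            for i in range(5):
                for j in range(5):
                    xi, xj = X[i], X[j]
                    if spec.family == "linear":
                        exp = xi @ xj
                    elif spec.family == "polynomial":
                        exp = (xi @ xj / 3 + 1) ** 3
                    else:
                        exp = np.exp(-((xi - xj) ** 2).sum() / (2 * 0.8**2))
                    assert K[i, j] == pytest.approx(exp, rel=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            M.compute_kernel(np.zeros((2, 3)), np.zeros((2, 4)), M.KernelSpec("linear"))


def _enumerate_combine(bases, eta, degree):
    """Independent multi-index enumeration of the polynomial combination."""
    p = len(bases)
    out = np.zeros_like(bases[0], dtype=float)
    for ks in itertools.product(range(degree + 1), repeat=p):
        if sum(ks) != degree:
            continue
        term = np.ones_like(out)
        coeff = 1.0
        for m, k in enumerate(ks):
            coeff *= eta[m] ** k
            for _ in range(k):
                term = term * bases[m]
        out += coeff * term
    return out


class TestCombine:
    def test_single_base_passthrough_and_power(self):
        K = np.array([[2.0, 1.0], [1.0, 2.0]])
        assert np.allclose(M.nlmkl_combine([K], np.array([1.0]), 1), K)
        assert np.allclose(M.nlmkl_combine([K], np.array([1.0]), 2), K * K)

    def test_two_base_degree_two_example(self):
        K1, K2 = np.eye(2), np.ones((2, 2))
        out = M.nlmkl_combine([K1, K2], np.array([1.0, 1.0]), 2)
        assert np.allclose(out, [[3.0, 1.0], [1.0, 3.0]])

    @pytest.mark.parametrize("degree", [1, 2, 3])
    def test_matches_multi_index_enumeration(self, degree):
        rng = np.random.default_rng(2)
        bases = [A @ A.T for A in (rng.random((2, 3)) for _ in range(3))]
        eta = rng.uniform(0.1, 1.0, 3)
        assert np.allclose(
            M.nlmkl_combine(bases, eta, degree),
            _enumerate_combine(bases, eta, degree),
            rtol=1e-12,
        )

    def test_preserves_positive_semidefiniteness(self):
        rng = np.random.default_rng(3)
        bases = [A @ A.T for A in (rng.random((6, 4)) for _ in range(4))]
        eta = rng.uniform(0, 1, 4)
        out = M.nlmkl_combine(bases, eta, 2)
        assert np.linalg.eigvalsh(out).min() >= -1e-8

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            M.nlmkl_combine([np.eye(2)], np.array([-0.1]), 2)

    def test_gradient_fast_path_matches_enumeration(self):
        rng = np.random.default_rng(4)
        bases = [A @ A.T for A in (rng.random((5, 3)) for _ in range(3))]
        eta = rng.uniform(0.2, 0.9, 3)
        beta = rng.normal(0, 1, 5)
        fast = M._grad_quadform(bases, eta, 2, beta)
        eps = 1e-7
        for m in range(3):
            ep = eta.copy()
            ep[m] += eps
            num = (
                beta @ _enumerate_combine(bases, ep, 2) @ beta
                - beta @ _enumerate_combine(bases, eta, 2) @ beta
            ) / eps
            assert fast[m] == pytest.approx(num, rel=1e-5)


def _qp_dual_reference(K, y, C):
    """Box-constrained SVM dual solved by SLSQP (independent oracle)."""
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K

    def neg_obj(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def grad(a):
        return -(np.ones(n) - Q @ a)

    res = minimize(
        neg_obj,
        np.full(n, C / 10),
        jac=grad,
        bounds=[(0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return -res.fun


class TestTraining:
    def test_degenerate_single_kernel_matches_qp_reference(self):
        """One group, one family, η ≡ 1, degree 1: the dual objective agrees
        with an independent quadratic-program solution to 1e-6."""
        groups, y = _two_class_groups(seed=5, n_per=10)
        X = groups.groups["informative"]
        single = FeatureGroupSet(groups={"all": X}, labels=groups.labels)
        model = M.train_nlmkl(single, y, families=["gaussian"], C=1.0, degree=1, max_iter=0)
        assert np.allclose(model.problems[0].eta, [1.0])
        # rebuild the exact kernel the model used
        Xz = model.train_groups["all"]
        spec = model.specs[0]
        K = M.compute_kernel(Xz, Xz, spec) / spec.trace_factor
        ybin = np.where(y == model.problems[0].positive_class, 1.0, -1.0)
        ref = _qp_dual_reference(K, ybin, C=1.0)
        impl = model.problems[0].objective_trace[-1]
        assert abs(impl - ref) <= 1e-6 * max(1.0, abs(ref))

    def test_informative_group_gets_larger_weights(self):
        hits = 0
        for seed in range(5):
            groups, y = _two_class_groups(seed=seed, n_per=40)
            model = M.train_nlmkl(groups, y, families=["gaussian"], C=10.0)
            eta = model.problems[0].eta
            # base order: (group, family) sorted -> informative first
            if eta[0] > eta[1]:
                hits += 1
        assert hits >= 4

    def test_separable_points_reach_perfect_training_accuracy(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 10.0], [10.0, 11.0]])
        y = ["a", "a", "b", "b"]
        g = FeatureGroupSet(groups={"all": X}, labels=y)
        model = M.train_nlmkl(g, y, C=100.0)
        assert M.predict(model, g) == y

    def test_objective_trace_is_monotone(self):
        groups, y = _two_class_groups(seed=7, n_per=25)
        model = M.train_nlmkl(groups, y, C=10.0)
        for prob in model.problems:
            diffs = np.diff(prob.objective_trace)
            assert np.all(diffs <= 1e-6)

    def test_combined_kernel_psd_at_learned_weights(self):
        groups, y = _two_class_groups(seed=9, n_per=15)
        model = M.train_nlmkl(groups, y, C=10.0)
        tables = model.train_groups
        bases = []
        for spec in model.specs:
            K = M.compute_kernel(tables[spec.group], tables[spec.group], spec)
            bases.append(K / spec.trace_factor)
        for K in bases:
            assert np.linalg.eigvalsh(K).min() >= -1e-8
        for prob in model.problems:
            Kc = M.nlmkl_combine(bases, prob.eta, model.degree)
            assert np.linalg.eigvalsh(Kc).min() >= -1e-8

    def test_non_finite_features_rejected(self):
        g = FeatureGroupSet(groups={"a": np.array([[1.0], [np.nan]])}, labels=["x", "y"])
        with pytest.raises(ValueError):
            M.train_nlmkl(g, ["x", "y"])


class TestPrediction:
    def test_decision_values_match_scalar_reimplementation(self):
        """f(x) = Σ α_i y_i K_η(x_i, x) + b evaluated by an explicit loop."""
        groups, y = _two_class_groups(seed=11, n_per=8)
        model = M.train_nlmkl(groups, y, families=["linear", "gaussian"], C=10.0)
        test = FeatureGroupSet(
            groups={g: t[:3] for g, t in groups.groups.items()},
            labels=groups.labels[:3],
        )
        dv = M.decision_values(model, test)
        tables, _ = M._prepare_groups(test, scalers=model.scalers)
        prob = model.problems[0]
        for s in range(3):
            acc = 0.0
            for i in range(len(y)):
                bases_ij = []
                for spec in model.specs:
                    k = M.compute_kernel(
                        tables[spec.group][s : s + 1],
                        model.train_groups[spec.group][i : i + 1],
                        spec,
                    )[0, 0]
                    bases_ij.append(k / spec.trace_factor)
                k_eta = _enumerate_combine(
                    [np.array([[b]]) for b in bases_ij], prob.eta, model.degree
                )[0, 0]
                acc += prob.beta[i] * k_eta
            assert dv[s, 0] == pytest.approx(acc + prob.bias, rel=1e-9, abs=1e-9)

    def test_prediction_permutation_equivariance(self):
        groups, y = _two_class_groups(seed=13, n_per=12)
        model = M.train_nlmkl(groups, y, families=["gaussian"], C=10.0)
        perm = np.random.default_rng(0).permutation(len(y))
        pred = M.predict(model, groups)
        pred_perm = M.predict(model, groups.subset(perm))
        assert [pred[i] for i in perm] == pred_perm

    def test_group_roster_mismatch_raises(self):
        groups, y = _two_class_groups(seed=15, n_per=8)
        model = M.train_nlmkl(groups, y, families=["linear"], C=1.0)
        with pytest.raises(ValueError):
            M.predict(model, FeatureGroupSet(groups={"other": np.zeros((2, 3))}))


def test_svm_single_equals_degenerate_mkl():
    groups, y = _two_class_groups(seed=17, n_per=10)
    X = np.hstack([groups.groups["informative"], groups.groups["noise"]])
    svm = M.train_svm_single(X, y, family="polynomial", C=10.0)
    mkl = M.train_nlmkl(
        FeatureGroupSet(groups={"all": X}),
        y,
        families=["polynomial"],
        C=10.0,
        degree=1,
        max_iter=0,
    )
    g = FeatureGroupSet(groups={"all": X})
    assert np.allclose(M.decision_values(svm, g), M.decision_values(mkl, g), atol=1e-6)


def test_c_grid_values_accepted():
    groups, y = _two_class_groups(seed=19, n_per=8)
    X = groups.groups["informative"]
    for C in (1.0, 10.0, 100.0):
        model = M.train_svm_single(X, y, family="gaussian", C=C)
        assert model.C == C
        assert np.isfinite(model.specs[0].width)
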