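"""Linear SVM, fold partitioning, and cross-validation error."""

import numpy as np
import pytest

from nirsweep import (
    LinearModel,
    accuracy_from_errors,
    cross_validation_error,
    decision_value,
    fit_linear_svm,
    kfold_partition,
    predict,
)
from nirsweep.classify import _svm_weights

from conftest import make_dataset


def margin_of(w, b, X, t):
    return np.min(t * (X @ w + b)) / np.linalg.norm(w)


def brute_force_margin(X, t, n_angles=2000, n_offsets=801):
    """Grid maximizer of the geometric margin over unit directions and
    offsets — an oracle independent of the QP solver (2-D only)."""
    best = -np.inf
    r = np.max(np.abs(X)) * 2
    for theta in np.linspace(0, np.pi, n_angles):
        u = np.array([np.cos(theta), np.sin(theta)])
        proj = X @ u
        for b in np.linspace(-r, r, n_offsets):
            m = np.min(t * (proj + b))
            best = max(best, m)
    return best


class TestFitLinearSVM:
    def test_symmetric_1d_boundary_at_zero(self):
        model = fit_linear_svm([[-1.0], [1.0]], [-1, 1], C=1e6)
        assert model.w[0] > 0
        assert model.b == pytest.approx(0.0, abs=1e-6)
        # x = 0 sits exactly on the boundary; ties resolve to -1
        assert predict(model, [0.0]) == -1

    def test_xor_layout_not_separable(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        t = np.array([1, 1, -1, -1])
        model = fit_linear_svm(X, t, C=1e6)
        preds = [predict(model, x) for x in X]
        assert np.sum(np.asarray(preds) != t) > 0

    def test_margin_matches_bruteforce_oracle(self, separable_2d):
        X, t = separable_2d
        model = fit_linear_svm(X, t, C=1e6)
        assert margin_of(model.w, model.b, X, t) == pytest.approx(
            brute_force_margin(X, t), rel=0.02
        )

    def test_hard_margin_separates_training_points(self, separable_2d):
        X, t = separable_2d
        model = fit_linear_svm(X, t, C=1e6)
        assert np.all(t * (X @ model.w + model.b) > 0)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="class"):
            fit_linear_svm([[0.0], [1.0]], [1, 1])

    def test_non_finite_errors(self):
        with pytest.raises(ValueError, match="finite"):
            fit_linear_svm([[np.nan], [1.0]], [-1, 1])

    def test_label_flip_negates_solution(self, separable_2d):
        X, t = separable_2d
        m1 = fit_linear_svm(X, t, C=1e6)
        m2 = fit_linear_svm(X, -t, C=1e6)
        np.testing.assert_allclose(m1.w, -m2.w, rtol=1e-4, atol=1e-8)
        assert m1.b == pytest.approx(-m2.b, rel=1e-4, abs=1e-8)

    def test_fast_path_matches_public_svc(self):
        """Dual-route safeguard: the direct libsvm fast path must agree
        with sklearn's SVC exactly, for both label orderings."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(1)
        for trial in range(40):
            n, d = int(rng.integers(6, 40)), int(rng.integers(1, 8))
            X = np.ascontiguousarray(rng.normal(size=(n, d)))
            t = rng.choice([-1.0, 1.0], size=n)
            if np.unique(t).size < 2:
                continue
            C = float(rng.choice([0.1, 1.0, 10.0]))
            w, b = _svm_weights(X, t, C)
            clf = SVC(kernel="linear", C=C).fit(X, t)
            np.testing.assert_allclose(w, clf.coef_.ravel(), atol=1e-10)
            assert b == pytest.approx(float(clf.intercept_[0]), abs=1e-10)


class TestDecisionPredict:
    model = LinearModel(w=np.array([1.0, -1.0]), b=0.0, subset=(1, 2))

    def test_direct_arithmetic(self):
        assert decision_value(self.model, [2.0, 1.0]) == pytest.approx(1.0)
        assert predict(self.model, [2.0, 1.0]) == 1

    def test_tie_goes_to_negative_class(self):
        assert predict(self.model, [1.0, 1.0]) == -1

    def test_zero_weights_negative_intercept(self):
        m = LinearModel(w=np.zeros(2), b=-3.0, subset=(1, 2))
        assert predict(m, [100.0, 100.0]) == -1

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            decision_value(self.model, [1.0, 2.0, 3.0])


class TestKFold:
    def test_balanced_50_5(self):
        t = np.array([1] * 25 + [-1] * 25)
        folds = kfold_partition(50, 5, t, seed=0)
        for k in range(1, 6):
            rows = folds.test_rows(k)
            assert rows.size == 10
            assert np.sum(t[rows] == 1) == 5

    def test_leave_one_out_degenerate(self):
        t = np.array([1] * 5 + [-1] * 5)
        folds = kfold_partition(10, 10, t, seed=1)
        assert all(folds.test_rows(k).size == 1 for k in range(1, 11))

    def test_same_seed_identical(self):
        t = np.array([1] * 10 + [-1] * 12)
        a = kfold_partition(22, 5, t, seed=9)
        b = kfold_partition(22, 5, t, seed=9)
        np.testing.assert_array_equal(a.fold_of_row, b.fold_of_row)

    def test_k_exceeding_n_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            kfold_partition(4, 5, np.array([1, 1, -1, -1]), seed=0)


class TestCrossValidation:
    def test_separated_data_perfect_accuracy(self, separable_2d):
        X, t = separable_2d
        ds = make_dataset(X, t)
        folds = kfold_partition(ds.n, 5, ds.t, seed=0)
        cv = cross_validation_error(ds, (1, 2), folds)
        assert cv.cve == 0.0 and cv.accuracy_percent == 100.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(200, 4))
        X[:100] += 2.0  # informative structure, but labels get shuffled
        t = rng.permutation([1] * 100 + [-1] * 100)
        ds = make_dataset(X, t)
        folds = kfold_partition(ds.n, 5, ds.t, seed=0)
        cv = cross_validation_error(ds, ds.channel_ids, folds)
        assert 35.0 <= cv.accuracy_percent <= 65.0

    def test_accuracy_identity(self, planted_small, planted_small_folds):
        ds, _ = planted_small
        cv = cross_validation_error(ds, ds.channel_ids, planted_small_folds)
        n_err = sum(cv.per_fold_errors)
        assert cv.cve == n_err / ds.n
        assert cv.accuracy_percent == (1.0 - cv.cve) * 100.0

    def test_eight_errors_in_fifty_is_84_percent(self):
        assert accuracy_from_errors(8, 50) == pytest.approx(84.0)

    def test_column_scaling_leaves_predictions(self, separable_2d):
        X, t = separable_2d
        folds = kfold_partition(len(t), 5, t, seed=0)
        a = cross_validation_error(make_dataset(X, t), (1, 2), folds, C=1e6)
        X2 = X.copy()
        X2[:, 0] *= 7.5
        b = cross_validation_error(make_dataset(X2, t), (1, 2), folds, C=1e6)
        np.testing.assert_array_equal(a.predictions, b.predictions)

    def test_single_class_training_split_names_fold(self):
        X = np.arange(8, dtype=float).reshape(-1, 1)
        t = np.array([1, 1, 1, 1, 1, 1, 1, -1])
        ds = make_dataset(X, t)
        folds = kfold_partition(8, 4, ds.t, seed=0)
        with pytest.raises(ValueError, match="fold"):
            cross_validation_error(ds, (1,), folds)
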