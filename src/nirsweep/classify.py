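"""Linear maximum-margin classifier and K-fold cross-validation error.

This is the scoring engine of the subset search: a soft-margin linear
SVM (decision rule ``sign(w.x + b)``), a seeded label-stratified K-fold
partition, and the cross-validation error

    CVE = (# held-out misclassifications) / N,
    accuracy% = (1 - CVE) * 100.

The solver is libsvm via scikit-learn. Because the exhaustive search
refits the SVM tens of thousands of times on tiny matrices, a low-level
fast path calls libsvm directly, bypassing per-call estimator
validation; it is verified equivalent to :class:`sklearn.svm.SVC` by a
dedicated test and falls back to the public API if unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

try:  # fast path: direct libsvm binding (same solver SVC wraps)
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - exercised only on older sklearn
    _libsvm = None

DEFAULT_C = 1.0


@dataclass
class LinearModel:
    """Linear decision boundary y(x) = w.x + b over a channel subset.

    The weight sign is interpretable: a positive ``w[j]`` means larger
    values of that channel's feature push the decision toward the +1
    group, a negative one toward the -1 group.
    """

    w: np.ndarray
    b: float
    subset: tuple[int, ...]
    C: float = DEFAULT_C

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        self.subset = tuple(int(c) for c in self.subset)
        if self.w.size != len(self.subset) or self.w.size < 1:
            raise ValueError("weight length must equal subset size >= 1")
        if not np.all(np.isfinite(self.w)) or not np.isfinite(self.b):
            raise ValueError("non-finite model parameters")


@dataclass
class FoldAssignment:
    """Partition of N rows into K folds, stratified by label."""

    K: int
    fold_of_row: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.fold_of_row = np.asarray(self.fold_of_row, dtype=int)
        counts = np.bincount(self.fold_of_row, minlength=self.K + 1)[1:]
        if len(counts) != self.K or (counts == 0).any():
            raise ValueError("every fold must be nonempty")

    def test_rows(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_row == k)

    def train_rows(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_row != k)


@dataclass
class CVResult:
    """Cross-validation outcome for one channel subset."""

    cve: float
    accuracy_percent: float
    per_fold_errors: tuple[int, ...]
    predictions: np.ndarray
    seed: int | None = None
    C: float = DEFAULT_C

    def to_dict(self) -> dict:
        return {
            "cve": self.cve,
            "accuracy_percent": self.accuracy_percent,
            "per_fold_errors": list(self.per_fold_errors),
            "seed": self.seed,
            "C": self.C,
        }


def accuracy_from_errors(n_errors: int, n: int) -> float:
    """Classification accuracy in percent from an error count:
    ``(1 - n_errors/n) * 100``."""
    if not 0 <= n_errors <= n:
        raise ValueError("need 0 <= n_errors <= n")
    return (1.0 - n_errors / n) * 100.0


def _validate_Xt(X: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    t = np.asarray(t, dtype=np.float64).ravel()
    if t.size != X.shape[0]:
        raise ValueError("label length mismatch")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    if not np.all(np.isin(t, (-1.0, 1.0))):
        raise ValueError("labels must be +1/-1")
    if np.unique(t).size < 2:
        raise ValueError("both classes must be present")
    return X, t


def _svm_weights(X: np.ndarray, t: np.ndarray, C: float) -> tuple[np.ndarray, float]:
    """(w, b) in the sklearn orientation: decision > 0 predicts +1."""
    if _libsvm is not None:
        res = _libsvm.fit(X, t, svm_type=0, kernel="linear", C=float(C))
        # res = (support, SV, n_support, dual_coef, rho, ...); SVC's
        # (coef_, intercept_) equal (-dual_coef @ SV, -rho) for +/-1 labels
        w = -(res[3] @ res[1]).ravel()
        b = -float(res[4][0])
        return w, b
    clf = SVC(kernel="linear", C=float(C)).fit(X, t)
    return clf.coef_.ravel(), float(clf.intercept_[0])


def fit_linear_svm(
    X: np.ndarray,
    t: np.ndarray,
    C: float = DEFAULT_C,
    subset: Sequence[int] | None = None,
) -> LinearModel:
    """Fit the soft-margin linear SVM.

    With separable data and large ``C`` the solution approaches the
    hard-margin classifier, i.e. every training sample ends up on its
    own side of the boundary (t * y(x) > 0).
    """
    if C <= 0:
        raise ValueError("C must be positive")
    X, t = _validate_Xt(X, t)
    w, b = _svm_weights(X, t, C)
    ids = tuple(subset) if subset is not None else tuple(range(X.shape[1]))
    return LinearModel(w=w, b=b, subset=ids, C=C)


def decision_value(model: LinearModel, x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float).ravel()
    if x.size != model.w.size:
        raise ValueError(
            f"feature length {x.size} != subset size {model.w.size}"
        )
    return float(model.w @ x + model.b)


def predict(model: LinearModel, x: np.ndarray) -> int:
    """Class of ``x``; the boundary itself (y = 0) maps to -1."""
    return 1 if decision_value(model, x) > 0 else -1


def kfold_partition(
    N: int, K: int, t: np.ndarray, seed: int
) -> FoldAssignment:
    """Seeded label-stratified K-fold partition.

    Within each label, shuffled rows are dealt one at a time to the
    currently smallest fold, so per-label fold counts differ by at most
    one and ``K = N`` degenerates to leave-one-out. Deterministic for a
    given seed.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > N:
        raise ValueError(f"K={K} exceeds N={N}")
    t = np.asarray(t).ravel()
    if t.size != N:
        raise ValueError("label length mismatch")
    rng = np.random.default_rng(seed)
    fold_of_row = np.zeros(N, dtype=int)
    sizes = np.zeros(K, dtype=int)
    for label in (+1, -1):
        rows = np.flatnonzero(t == label)
        rng.shuffle(rows)
        for r in rows:
            k = int(np.argmin(sizes))
            fold_of_row[r] = k + 1
            sizes[k] += 1
    return FoldAssignment(K=K, fold_of_row=fold_of_row, seed=seed)


def cross_validation_error(
    dataset,
    subset: Sequence[int],
    folds: FoldAssignment,
    C: float = DEFAULT_C,
) -> CVResult:
    """K-fold CVE of the linear SVM restricted to one channel subset.

    For each fold k the SVM is trained on the rows outside the fold
    using only the columns in ``subset``, and the held-out rows are
    predicted; a prediction on the wrong side of (or exactly on) the
    boundary counts as one error.
    """
    subset = tuple(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    cols = [dataset.channel_ids.index(c) for c in subset]
    X = np.ascontiguousarray(dataset.X[:, cols])
    t = dataset.t.astype(np.float64)
    N = t.size

    predictions = np.zeros(N, dtype=int)
    per_fold: list[int] = []
    for k in range(1, folds.K + 1):
        tr, te = folds.train_rows(k), folds.test_rows(k)
        t_tr = t[tr]
        if np.unique(t_tr).size < 2:
            raise ValueError(
                f"training split for fold {k} contains a single class; "
                "re-seed the fold assignment"
            )
        w, b = _svm_weights(np.ascontiguousarray(X[tr]), t_tr, C)
        dv = X[te] @ w + b
        pred = np.where(dv > 0, 1, -1)
        predictions[te] = pred
        per_fold.append(int(np.sum(pred != t[te])))

    cve = sum(per_fold) / N
    return CVResult(
        cve=cve,
        accuracy_percent=accuracy_from_errors(sum(per_fold), N),
        per_fold_errors=tuple(per_fold),
        predictions=predictions,
        seed=folds.seed,
        C=C,
    )
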