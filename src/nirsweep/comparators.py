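"""Embedded sparse feature-selection baselines: LASSO and sparse logistic.

These are the methods the exhaustive search is benchmarked against:
instead of scoring every channel subset explicitly, they select channels
implicitly during a single penalized fit. The LASSO here is the
classical L1-penalized least-squares regression onto the +/-1 labels,
used as a classifier through the sign of its linear predictor. The
sparse logistic classifier is an L1-penalized logistic regression with
the penalty chosen by inner cross-validation — a functional stand-in
for automatic-relevance-determination sparse logistic regression,
preserving the embedded-selection role without the variational
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.linear_model import Lasso, LinearRegression, LogisticRegression

from .classify import FoldAssignment, LinearModel, kfold_partition
from .preprocess import FeatureDataset

# Log-spaced penalty grids for the inner CV. Lasso alphas follow
# sklearn's (1/2n)||r||^2 + alpha*||w||_1 convention; logistic C is the
# inverse penalty strength, floored at 1e-3 so perfect separation never
# sends the weights to infinity.
LASSO_ALPHA_GRID: tuple[float, ...] = tuple(np.logspace(-3, 0.5, 15))
LOGISTIC_C_GRID: tuple[float, ...] = tuple(np.logspace(-2, 2, 13))


@dataclass
class ComparatorResult:
    method: str
    accuracy_percent: float
    selected_channels: tuple[int, ...]
    weights: np.ndarray
    intercept: float
    hyperparameter_trace: tuple[float, ...]
    predictions: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "accuracy_percent": self.accuracy_percent,
            "selected_channels": list(self.selected_channels),
            "weights": [float(w) for w in self.weights],
            "intercept": self.intercept,
            "hyperparameter_trace": list(self.hyperparameter_trace),
        }


def _check(X: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite input")
    return X, t


def fit_lasso_classifier(
    X: np.ndarray,
    t: np.ndarray,
    lam: float,
    subset: Sequence[int] | None = None,
) -> LinearModel:
    """L1-penalized least squares onto +/-1 targets.

    Minimizes ``(1/2n)||t - b - Xw||^2 + lam * sum|w_j|``; ``lam = 0``
    reduces to ordinary least squares. The L1 penalty produces exact
    zeros, so the nonzero coordinates are the selected channels.
    Prediction is ``sign(w.x + b)``.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X, t = _check(X, t)
    if lam == 0:
        est = LinearRegression().fit(X, t)
    else:
        est = Lasso(alpha=lam, max_iter=50_000).fit(X, t)
    ids = tuple(subset) if subset is not None else tuple(range(X.shape[1]))
    return LinearModel(
        w=np.asarray(est.coef_, dtype=float),
        b=float(est.intercept_),
        subset=ids,
        C=lam,
    )


def fit_sparse_logistic(
    X: np.ndarray,
    t: np.ndarray,
    C: float | None = None,
    inner_K: int = 5,
    seed: int = 0,
    subset: Sequence[int] | None = None,
) -> LinearModel:
    """L1-penalized logistic regression with inner-CV penalty choice.

    When ``C`` is None it is chosen by ``inner_K``-fold CV accuracy over
    a log grid, ties resolved toward the smaller (sparser) ``C``. Exact
    zeros in the weights mark de-selected channels.
    """
    X, t = _check(X, t)
    if np.unique(t).size < 2:
        raise ValueError("both classes must be present")
    if C is None:
        C = _select_logistic_C(X, t, inner_K=inner_K, seed=seed)
    est = LogisticRegression(
        solver="liblinear", l1_ratio=1.0, C=float(C), max_iter=5_000,
        random_state=0,  # liblinear shuffles internally; pin it
    ).fit(X, t)
    # orient so the decision is w.x + b > 0 => class +1
    sign = 1.0 if est.classes_[-1] == 1 else -1.0
    ids = tuple(subset) if subset is not None else tuple(range(X.shape[1]))
    return LinearModel(
        w=sign * np.asarray(est.coef_, dtype=float).ravel(),
        b=sign * float(est.intercept_[0]),
        subset=ids,
        C=float(C),
    )


def _cv_accuracy_of(
    fitter, X: np.ndarray, t: np.ndarray, folds: FoldAssignment
) -> float:
    errors = 0
    for k in range(1, folds.K + 1):
        tr, te = folds.train_rows(k), folds.test_rows(k)
        model = fitter(X[tr], t[tr])
        dv = X[te] @ model.w + model.b
        pred = np.where(dv > 0, 1.0, -1.0)
        errors += int(np.sum(pred != t[te]))
    return (1.0 - errors / t.size) * 100.0


def _select_lasso_alpha(
    X: np.ndarray,
    t: np.ndarray,
    grid: Sequence[float] = LASSO_ALPHA_GRID,
    inner_K: int = 5,
    seed: int = 0,
) -> float:
    folds = kfold_partition(t.size, min(inner_K, t.size), t, seed)
    best, best_acc = None, -1.0
    for lam in sorted(grid, reverse=True):  # ties -> sparser (larger lam)
        acc = _cv_accuracy_of(
            lambda A, y, lam=lam: fit_lasso_classifier(A, y, lam), X, t, folds
        )
        if acc > best_acc:
            best, best_acc = lam, acc
    return float(best)


def _select_logistic_C(
    X: np.ndarray,
    t: np.ndarray,
    grid: Sequence[float] = LOGISTIC_C_GRID,
    inner_K: int = 5,
    seed: int = 0,
) -> float:
    folds = kfold_partition(t.size, min(inner_K, t.size), t, seed)
    best, best_acc = None, -1.0
    for C in sorted(grid):  # ties -> smaller C (sparser)
        acc = _cv_accuracy_of(
            lambda A, y, C=C: fit_sparse_logistic(A, y, C=C), X, t, folds
        )
        if acc > best_acc:
            best, best_acc = C, acc
    return float(best)


def comparator_cv_accuracy(
    dataset: FeatureDataset,
    method: str,
    folds: FoldAssignment,
    inner_K: int = 5,
) -> ComparatorResult:
    """Outer-CV accuracy of an embedded method on the same folds as the
    exhaustive search.

    Per outer fold: the penalty is chosen by inner CV on the training
    rows only, the model refit on those rows, and the held-out rows
    predicted. The reported selected channels come from a final fit on
    all rows at the median of the per-fold penalties.
    """
    if method not in ("lasso", "slr"):
        raise ValueError("method must be 'lasso' or 'slr'")
    X = dataset.X
    t = dataset.t.astype(float)
    N = t.size
    errors = 0
    trace: list[float] = []
    predictions = np.zeros(N, dtype=int)
    for k in range(1, folds.K + 1):
        tr, te = folds.train_rows(k), folds.test_rows(k)
        if method == "lasso":
            lam = _select_lasso_alpha(
                X[tr], t[tr], inner_K=inner_K, seed=folds.seed + k
            )
            model = fit_lasso_classifier(X[tr], t[tr], lam)
            trace.append(lam)
        else:
            C = _select_logistic_C(
                X[tr], t[tr], inner_K=inner_K, seed=folds.seed + k
            )
            model = fit_sparse_logistic(X[tr], t[tr], C=C)
            trace.append(C)
        dv = X[te] @ model.w + model.b
        pred = np.where(dv > 0, 1, -1)
        predictions[te] = pred
        errors += int(np.sum(pred != t[te]))

    final_pen = float(np.median(trace))
    if method == "lasso":
        final = fit_lasso_classifier(X, t, final_pen)
    else:
        final = fit_sparse_logistic(X, t, C=final_pen)
    selected = tuple(
        dataset.channel_ids[j]
        for j in range(dataset.d)
        if final.w[j] != 0.0
    )
    return ComparatorResult(
        method=method,
        accuracy_percent=(1.0 - errors / N) * 100.0,
        selected_channels=selected,
        weights=final.w,
        intercept=final.b,
        hyperparameter_trace=tuple(trace),
        predictions=predictions,
    )
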