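"""Exhaustive channel-subset search.

Every nonempty subset of the D channels is scored by the K-fold
cross-validation error of a linear SVM restricted to that subset — a
wrapper feature selection with no approximation, feasible because fNIRS
arrays are small (2^12 - 1 = 4095 subsets per hemisphere, 2^24 - 1 =
16,777,215 bilaterally). The ranked results expose which channels the
best subsets keep re-using and whether their weight signs are stable,
which is the substantive readout: channels whose response separates the
two groups, and in which direction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .classify import DEFAULT_C, FoldAssignment, _svm_weights
from .preprocess import FeatureDataset

MAX_D = 30


@dataclass(frozen=True)
class ChannelSubset:
    """A subset encoded as a bitmask over the dataset's channel order."""

    mask: int
    channel_ids: tuple[int, ...]

    @staticmethod
    def from_mask(mask: int, all_ids: Sequence[int]) -> "ChannelSubset":
        if mask < 1:
            raise ValueError("mask must be >= 1")
        ids = tuple(
            all_ids[j] for j in range(len(all_ids)) if mask >> j & 1
        )
        return ChannelSubset(mask=mask, channel_ids=ids)

    @property
    def size(self) -> int:
        return len(self.channel_ids)


@dataclass
class SubsetEvaluation:
    subset: ChannelSubset
    cve: float
    accuracy_percent: float
    refit_weights: np.ndarray | None = None
    refit_intercept: float | None = None


@dataclass
class SearchReport:
    """Ranked outcome of one exhaustive run.

    ``optimal`` holds every subset attaining the minimal CVE; ``top_k``
    the first K after ranking (CVE ascending, then subset size, then
    mask). ``accuracy_distribution`` is the multiset of all accuracies,
    the reference against which embedded methods are percentile-ranked.
    """

    ranked: list[SubsetEvaluation]
    optimal: list[SubsetEvaluation]
    top_k: list[SubsetEvaluation]
    channel_occurrence: dict[int, int]
    sign_summary: dict[int, dict]
    accuracy_distribution: np.ndarray
    channel_ids: tuple[int, ...]
    k: int

    @property
    def best_accuracy_percent(self) -> float:
        return self.ranked[0].accuracy_percent

    def all_channels_evaluation(self) -> SubsetEvaluation:
        full = (1 << len(self.channel_ids)) - 1
        for ev in self.ranked:
            if ev.subset.mask == full:
                return ev
        raise ValueError("full-channel subset not among evaluations")

    def to_dict(self, max_ranked: int | None = None) -> dict:
        def enc(ev: SubsetEvaluation) -> dict:
            return {
                "mask": ev.subset.mask,
                "channels": list(ev.subset.channel_ids),
                "cve": ev.cve,
                "accuracy_percent": ev.accuracy_percent,
                "weights": None
                if ev.refit_weights is None
                else [float(w) for w in ev.refit_weights],
                "intercept": ev.refit_intercept,
            }

        ranked = self.ranked[:max_ranked] if max_ranked else self.ranked
        return {
            "channel_ids": list(self.channel_ids),
            "n_subsets": len(self.ranked),
            "best_accuracy_percent": self.best_accuracy_percent,
            "optimal": [enc(e) for e in self.optimal],
            "top_k": [enc(e) for e in self.top_k],
            "ranked_head": [enc(e) for e in ranked],
            "channel_occurrence": {
                str(c): n for c, n in self.channel_occurrence.items()
            },
            "sign_summary": {
                str(c): s for c, s in self.sign_summary.items()
            },
        }


def enumerate_subsets(
    D: int, channel_ids: Sequence[int] | None = None
) -> Iterator[ChannelSubset]:
    """Yield every nonempty subset of D channels in ascending mask order."""
    if not 1 <= D <= MAX_D:
        raise ValueError(f"D must be in 1..{MAX_D}")
    ids = tuple(channel_ids) if channel_ids is not None else tuple(
        range(1, D + 1)
    )
    if len(ids) != D:
        raise ValueError("channel_ids length must equal D")
    for mask in range(1, 1 << D):
        yield ChannelSubset.from_mask(mask, ids)


def _fold_views(dataset: FeatureDataset, folds: FoldAssignment):
    X = np.ascontiguousarray(dataset.X)
    t = dataset.t.astype(np.float64)
    views = []
    for k in range(1, folds.K + 1):
        tr, te = folds.train_rows(k), folds.test_rows(k)
        t_tr = t[tr]
        if np.unique(t_tr).size < 2:
            raise ValueError(
                f"training split for fold {k} contains a single class"
            )
        views.append(
            (np.ascontiguousarray(X[tr]), t_tr, np.ascontiguousarray(X[te]), t[te])
        )
    return X, t, views


def iter_subset_evaluations(
    dataset: FeatureDataset,
    folds: FoldAssignment,
    C: float = DEFAULT_C,
    masks: Iterable[int] | None = None,
    refit: bool = True,
) -> Iterator[SubsetEvaluation]:
    """Score subsets one by one with a fixed fold assignment.

    The same folds are reused for every subset so accuracies are
    directly comparable across subsets and the accuracy distribution is
    well defined. ``refit_weights`` come from a fit on the full dataset
    restricted to the subset (the reporting convention for the weight
    matrices and sign summaries).
    """
    D = dataset.d
    ids = dataset.channel_ids
    N = dataset.n
    X, t, views = _fold_views(dataset, folds)
    if masks is None:
        masks = range(1, 1 << D)
    for mask in masks:
        if not 1 <= mask < (1 << D):
            raise ValueError(f"mask {mask} out of range for D={D}")
        cols = [j for j in range(D) if mask >> j & 1]
        errors = 0
        try:
            for X_tr, t_tr, X_te, t_te in views:
                w, b = _svm_weights(
                    np.ascontiguousarray(X_tr[:, cols]), t_tr, C
                )
                dv = X_te[:, cols] @ w + b
                pred = np.where(dv > 0, 1.0, -1.0)
                errors += int(np.sum(pred != t_te))
        except Exception as exc:
            raise RuntimeError(f"subset mask={mask}: {exc}") from exc
        cve = errors / N
        ev = SubsetEvaluation(
            subset=ChannelSubset.from_mask(mask, ids),
            cve=cve,
            accuracy_percent=(1.0 - cve) * 100.0,
        )
        if refit:
            w, b = _svm_weights(np.ascontiguousarray(X[:, cols]), t, C)
            ev.refit_weights, ev.refit_intercept = w, float(b)
        yield ev


def evaluate_all_subsets(
    dataset: FeatureDataset,
    folds: FoldAssignment,
    C: float = DEFAULT_C,
    refit: bool = True,
    mask_range: tuple[int, int] | None = None,
    checkpoint_path: str | None = None,
    checkpoint_every: int = 100_000,
) -> list[SubsetEvaluation]:
    """Evaluate every nonempty subset (or a mask shard) of the dataset.

    ``mask_range = (lo, hi)`` evaluates masks in ``[lo, hi)`` so a big
    run can be sharded; concatenating shard outputs equals the unsharded
    run. With ``checkpoint_path``, partial results are flushed to an
    ``.npz`` every ``checkpoint_every`` subsets and a re-run resumes
    from the last flush, yielding the identical final result.
    """
    D = dataset.d
    lo, hi = mask_range if mask_range else (1, 1 << D)
    if not (1 <= lo < hi <= 1 << D):
        raise ValueError("invalid mask range")

    done_masks: list[int] = []
    done_err: list[int] = []
    done_w: list[np.ndarray] = []
    done_b: list[float] = []
    start = lo
    if checkpoint_path and os.path.exists(checkpoint_path):
        ck = np.load(checkpoint_path, allow_pickle=False)
        done_masks = [int(m) for m in ck["masks"]]
        done_err = [int(e) for e in ck["errors"]]
        if "weights" in ck:
            W = ck["weights"]
            done_b = [float(v) for v in ck["intercepts"]]
            done_w = [W[i][~np.isnan(W[i])] for i in range(W.shape[0])]
        if done_masks:
            start = done_masks[-1] + 1

    def flush() -> None:
        if not checkpoint_path:
            return
        W = np.full((len(done_masks), D), np.nan)
        for i, (m, w) in enumerate(zip(done_masks, done_w)):
            cols = [j for j in range(D) if m >> j & 1]
            if len(w):
                W[i, cols] = w
        payload = {
            "masks": np.asarray(done_masks, dtype=np.int64),
            "errors": np.asarray(done_err, dtype=np.int64),
        }
        if refit:
            payload["weights"] = W
            payload["intercepts"] = np.asarray(done_b)
        tmp = checkpoint_path + ".tmp.npz"  # np.savez enforces the suffix
        np.savez(tmp, **payload)
        os.replace(tmp, checkpoint_path)

    N = dataset.n
    for i, ev in enumerate(
        iter_subset_evaluations(
            dataset, folds, C=C, masks=range(start, hi), refit=refit
        )
    ):
        done_masks.append(ev.subset.mask)
        done_err.append(round(ev.cve * N))
        done_w.append(
            ev.refit_weights if ev.refit_weights is not None else np.array([])
        )
        done_b.append(
            ev.refit_intercept if ev.refit_intercept is not None else np.nan
        )
        if checkpoint_path and (i + 1) % checkpoint_every == 0:
            flush()
    flush()

    ids = dataset.channel_ids
    out = []
    for m, e, w, b in zip(done_masks, done_err, done_w, done_b):
        ev = SubsetEvaluation(
            subset=ChannelSubset.from_mask(m, ids),
            cve=e / N,
            accuracy_percent=(1.0 - e / N) * 100.0,
        )
        if refit and len(w):
            ev.refit_weights, ev.refit_intercept = np.asarray(w), float(b)
        out.append(ev)
    return out


def rank_subsets(
    evaluations: Sequence[SubsetEvaluation],
    top_k: int = 50,
    channel_ids: Sequence[int] | None = None,
) -> SearchReport:
    """Total-order ranking: CVE ascending, then subset size, then mask.

    Ties on CVE are common (accuracy is quantized at 1/N), so the order
    prefers parsimony (fewer channels) and is made total by the mask.
    ``optimal`` collects every evaluation attaining the minimal CVE.
    ``channel_ids`` fixes the channel universe for the occurrence and
    sign tables; by default it is the union over the evaluated subsets
    (which is the full array when the evaluation was exhaustive).
    """
    evaluations = list(evaluations)
    if not evaluations:
        raise ValueError("no evaluations to rank")
    ranked = sorted(
        evaluations, key=lambda e: (e.cve, e.subset.size, e.subset.mask)
    )
    best = ranked[0].cve
    optimal = [e for e in ranked if e.cve == best]
    top = ranked[: min(top_k, len(ranked))]
    if channel_ids is not None:
        ids = tuple(int(c) for c in channel_ids)
    else:
        ids = tuple(
            sorted({c for e in evaluations for c in e.subset.channel_ids})
        )
    occ = channel_occurrence(top, ids)
    has_weights = all(e.refit_weights is not None for e in top)
    signs = sign_consistency(top, ids) if has_weights else {}
    return SearchReport(
        ranked=ranked,
        optimal=optimal,
        top_k=top,
        channel_occurrence=occ,
        sign_summary=signs,
        accuracy_distribution=np.array(
            [e.accuracy_percent for e in evaluations]
        ),
        channel_ids=ids,
        k=len(top),
    )


def channel_occurrence(
    top_k: Sequence[SubsetEvaluation], channel_ids: Sequence[int]
) -> dict[int, int]:
    """How many of the top-K subsets contain each channel."""
    if not top_k:
        raise ValueError("empty top-k")
    return {
        c: sum(1 for e in top_k if c in e.subset.channel_ids)
        for c in channel_ids
    }


def sign_consistency(
    top_k: Sequence[SubsetEvaluation], channel_ids: Sequence[int]
) -> dict[int, dict]:
    """Refit-weight sign tally per channel across the top-K subsets.

    A channel is sign-consistent when every subset that includes it
    assigns its weight the same sign — the condition under which the
    direction of the group difference at that channel can be read off
    the classifier.
    """
    if not top_k:
        raise ValueError("empty top-k")
    out: dict[int, dict] = {}
    for c in channel_ids:
        pos = neg = absent = 0
        for e in top_k:
            if c not in e.subset.channel_ids:
                absent += 1
                continue
            if e.refit_weights is None:
                raise ValueError("refit weights required for sign summary")
            w = e.refit_weights[e.subset.channel_ids.index(c)]
            if w > 0:
                pos += 1
            elif w < 0:
                neg += 1
        out[c] = {
            "positive": pos,
            "negative": neg,
            "absent": absent,
            "consistent": (pos == 0) or (neg == 0),
        }
    return out


def percentile_rank(
    accuracy: float, accuracy_distribution: np.ndarray
) -> tuple[int, float]:
    """Rank of an accuracy within the exhaustive distribution.

    Rank 1 is the best; an accuracy is ranked just below every strictly
    greater one. Returns ``(rank, top_fraction)`` with
    ``top_fraction = rank / len(distribution)``.
    """
    dist = np.asarray(accuracy_distribution)
    if dist.size == 0:
        raise ValueError("empty accuracy distribution")
    rank = 1 + int(np.count_nonzero(dist > accuracy))
    return rank, rank / dist.size
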