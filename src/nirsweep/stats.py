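"""Channel-wise univariate screening with FDR correction.

The classical alternative to multivariate subset search: test each
channel's mean Z-score separately — a two-sample t-test for the group
difference and, within each group, a one-sample t-test against zero
(no change from baseline) — and control the family of 24 channel tests
with the Benjamini-Hochberg false-discovery-rate procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import FeatureDataset


@dataclass
class ChannelScreenResult:
    channel_id: int
    test: str  # "two_sample" | "one_sample_pos" | "one_sample_neg"
    t_statistic: float
    df: float
    p_value: float
    p_adjusted: float | None = None
    fdr_significant: bool | None = None

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def two_sample_t(
    a: np.ndarray, b: np.ndarray, pooled: bool = True
) -> tuple[float, float, float]:
    """Two-tailed two-sample t-test; pooled variance by default.

    Returns ``(t, df, p)``. With ``pooled`` the degrees of freedom are
    ``n_a + n_b - 2``; otherwise the Welch-Satterthwaite approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) != np.mean(b):
            raise ValueError("both groups degenerate with unequal means")
        df = a.size + b.size - 2 if pooled else float(a.size + b.size - 2)
        return 0.0, float(df), 1.0
    res = stats.ttest_ind(a, b, equal_var=pooled)
    df = a.size + b.size - 2 if pooled else float(res.df)
    return float(res.statistic), float(df), float(res.pvalue)


def two_sample_t_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
) -> tuple[float, float, float]:
    """Pooled two-sample t from summary statistics (sample SDs).

    Useful for published tables that report only group means and SDs.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    t = (mean_a - mean_b) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def one_sample_t(
    values: np.ndarray, mu0: float = 0.0
) -> tuple[float, float, float]:
    """Two-tailed one-sample t-test of the mean against ``mu0``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero sample SD")
    res = stats.ttest_1samp(x, mu0)
    return float(res.statistic), float(x.size - 1), float(res.pvalue)


def fdr_bh(
    p_values: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up at level ``q``.

    Returns ``(reject_flags, adjusted_p)``; adjusted p-values are
    monotone after sorting and each is >= its raw p-value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def _participant_means(dataset: FeatureDataset) -> FeatureDataset:
    if not dataset.provenance:
        raise ValueError("participant mode needs row provenance")
    order: list[str] = []
    rows: dict[str, list[int]] = {}
    for i, (pid, _) in enumerate(dataset.provenance):
        if pid not in rows:
            rows[pid] = []
            order.append(pid)
        rows[pid].append(i)
    X = np.vstack([dataset.X[rows[p]].mean(axis=0) for p in order])
    t = np.array([int(dataset.t[rows[p][0]]) for p in order])
    prov = tuple((p, 0) for p in order)
    return FeatureDataset(X, t, dataset.channel_ids, prov)


def channelwise_screen(
    dataset: FeatureDataset,
    q: float = 0.05,
    unit: str = "trial",
    pooled: bool = True,
) -> list[ChannelScreenResult]:
    """Per-channel t-tests with FDR correction across channels.

    Three test families, each corrected separately across the D
    channels: the group difference (two-sample), and each group's mean
    against zero (one-sample). ``unit='participant'`` first averages a
    participant's trials into one observation.
    """
    if unit not in ("trial", "participant"):
        raise ValueError("unit must be 'trial' or 'participant'")
    ds = dataset if unit == "trial" else _participant_means(dataset)
    pos = ds.X[ds.t == 1]
    neg = ds.X[ds.t == -1]

    families: dict[str, list[ChannelScreenResult]] = {}
    for name, runner in (
        ("two_sample", lambda j: two_sample_t(pos[:, j], neg[:, j], pooled)),
        ("one_sample_pos", lambda j: one_sample_t(pos[:, j], 0.0)),
        ("one_sample_neg", lambda j: one_sample_t(neg[:, j], 0.0)),
    ):
        results = []
        for j, ch in enumerate(ds.channel_ids):
            t_stat, df, p = runner(j)
            results.append(
                ChannelScreenResult(
                    channel_id=ch, test=name, t_statistic=t_stat, df=df,
                    p_value=p,
                )
            )
        reject, p_adj = fdr_bh([r.p_value for r in results], q=q)
        for r, rej, pa in zip(results, reject, p_adj):
            r.fdr_significant = bool(rej)
            r.p_adjusted = float(pa)
        families[name] = results

    return [r for fam in families.values() for r in fam]
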