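"""End-to-end study driver and consolidated report.

One call runs the whole analysis: preprocessing, per-hemisphere (and
optionally bilateral) exhaustive subset searches, the embedded-method
comparators percentile-ranked against the exhaustive distribution, and
the channel-wise FDR screen. All randomness flows from a single root
seed recorded in the report's provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import kfold_partition
from .comparators import comparator_cv_accuracy
from .io import read_long_tsv, write_features_tsv
from .preprocess import PreprocConfig, TrialRecord, build_dataset
from .search import evaluate_all_subsets, percentile_rank, rank_subsets
from .simulate import PRESETS, generate_timeseries_study
from .stats import channelwise_screen


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_tsv: str | None = None  # None -> simulate `preset`
    preset: str = "paperlike50x24"
    seed: int = 0
    preprocessing: PreprocConfig = field(default_factory=PreprocConfig)
    cv_k: int = 5
    svm_C: float = 1.0
    top_k: int = 50
    q: float = 0.05
    stats_unit: str = "trial"
    channel_sets: tuple[str, ...] = ("left", "right")
    include_bilateral: bool = False
    checkpoint_dir: str | None = None
    test_onset_s: float = 20.0

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "preprocessing" in raw and isinstance(raw["preprocessing"], dict):
            pp = dict(raw["preprocessing"])
            if "feature_window_s" in pp:
                pp["feature_window_s"] = tuple(pp["feature_window_s"])
            raw["preprocessing"] = PreprocConfig(**pp)
        if "channel_sets" in raw:
            raw["channel_sets"] = tuple(raw["channel_sets"])
        return RunConfig(**raw)

    def semantic_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("checkpoint_dir", None)  # where checkpoints live is not semantic
        return d

    def hash(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    dataset_summary: dict
    sections: dict
    comparators: dict
    screen: list[dict]
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _ledger_frame(evals) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mask": [e.subset.mask for e in evals],
            "size": [e.subset.size for e in evals],
            "cve": [e.cve for e in evals],
            "accuracy_percent": [e.accuracy_percent for e in evals],
        }
    )


def _topk_weight_frame(report) -> pd.DataFrame:
    rows = []
    for rank, ev in enumerate(report.top_k, start=1):
        row: dict = {
            "rank": rank,
            "mask": ev.subset.mask,
            "accuracy_percent": ev.accuracy_percent,
        }
        for ch in report.channel_ids:
            if ch in ev.subset.channel_ids and ev.refit_weights is not None:
                row[f"ch{ch}"] = ev.refit_weights[
                    ev.subset.channel_ids.index(ch)
                ]
            else:
                row[f"ch{ch}"] = np.nan  # absent from the subset
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    trials: Sequence[TrialRecord] | None = None,
    out_dir: str | Path | None = None,
) -> StudyReport:
    """Execute the full study and return (and optionally write) the report.

    Stage order: acquire trials (given, simulated preset, or long TSV)
    -> QC + feature extraction -> exhaustive search per channel set
    -> LASSO/SLR comparators on the same folds, percentile-ranked
    against each set's exhaustive distribution -> channel-wise screen.
    """
    cfg = config
    if trials is None:
        if cfg.input_tsv:
            trials = read_long_tsv(
                cfg.input_tsv, test_onset_s=cfg.test_onset_s
            )
        else:
            if cfg.preset not in PRESETS:
                raise ValueError(f"unknown preset {cfg.preset!r}")
            trials, _ = generate_timeseries_study(
                PRESETS[cfg.preset](), seed=cfg.seed, cfg=cfg.preprocessing
            )

    dataset, qc_log = build_dataset(trials, cfg.preprocessing)
    folds = kfold_partition(dataset.n, cfg.cv_k, dataset.t, cfg.seed)

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_features_tsv(dataset, out / "features.tsv")
        (out / "qc_log.txt").write_text("\n".join(qc_log) + "\n")

    sets = list(cfg.channel_sets)
    if cfg.include_bilateral and "bilateral" not in sets:
        sets.append("bilateral")

    sections: dict = {}
    comparators: dict = {}
    for name in ("left", "right", "bilateral"):
        if name not in sets:
            if name == "bilateral":
                sections[name] = {"skipped": True}
            continue
        sub = dataset.restrict(name)
        ck = (
            str(Path(cfg.checkpoint_dir) / f"{name}.npz")
            if cfg.checkpoint_dir
            else None
        )
        evals = evaluate_all_subsets(
            sub, folds, C=cfg.svm_C, checkpoint_path=ck
        )
        report = rank_subsets(evals, top_k=cfg.top_k)
        allch = report.all_channels_evaluation()
        sections[name] = {
            "n_channels": sub.d,
            "n_subsets": len(evals),
            "best_accuracy_percent": report.best_accuracy_percent,
            "all_channels_accuracy_percent": allch.accuracy_percent,
            "n_optimal": len(report.optimal),
            "optimal_subsets": [
                list(e.subset.channel_ids) for e in report.optimal
            ],
            "channel_occurrence_top_k": {
                str(c): v for c, v in report.channel_occurrence.items()
            },
            "sign_summary_top_k": {
                str(c): v for c, v in report.sign_summary.items()
            },
        }
        comparators[name] = {}
        for method in ("lasso", "slr"):
            res = comparator_cv_accuracy(sub, method, folds)
            rank, frac = percentile_rank(
                res.accuracy_percent, report.accuracy_distribution
            )
            comparators[name][method] = {
                **res.to_dict(),
                "rank_in_exhaustive": rank,
                "top_percent": 100.0 * frac,
            }
        if out is not None:
            _ledger_frame(evals).to_csv(
                out / f"{name}_ledger.tsv", sep="\t", index=False
            )
            _topk_weight_frame(report).to_csv(
                out / f"{name}_top{report.k}_weights.tsv",
                sep="\t",
                index=False,
                na_rep="NA",
            )

    screen = [
        r.to_dict()
        for r in channelwise_screen(dataset, q=cfg.q, unit=cfg.stats_unit)
    ]

    n_pos = int(np.sum(dataset.t == 1))
    report_obj = StudyReport(
        dataset_summary={
            "n_trials": dataset.n,
            "n_per_group": {"+1": n_pos, "-1": dataset.n - n_pos},
            "n_channels": dataset.d,
            "n_rejected_trials": len(trials) - dataset.n,
        },
        sections=sections,
        comparators=comparators,
        screen=screen,
        provenance={
            "seed": cfg.seed,
            "cv_k": cfg.cv_k,
            "svm_C": cfg.svm_C,
            "config_hash": cfg.hash(),
            "version": __version__,
        },
    )
    if out is not None:
        report_obj.to_json(out / "report.json")
        pd.DataFrame(screen).to_csv(out / "screen.tsv", sep="\t", index=False)
    return report_obj
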