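"""Plain-text I/O: long-form trial TSV, feature-matrix TSV, config files.

The interchange format for raw data is a long-form delimited table with
columns ``participant, group, trial, channel, time_s, oxyhb`` — one row
per sample. Missing samples are empty fields or NA. Feature matrices
travel as wide TSV with one row per trial.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .preprocess import FeatureDataset, TrialRecord

LONG_COLUMNS = ("participant", "group", "trial", "channel", "time_s", "oxyhb")


def write_long_tsv(trials: Sequence[TrialRecord], path: str | Path) -> None:
    frames = []
    for tr in trials:
        time_s = np.arange(tr.n_samples) * tr.sampling_interval
        for ch in sorted(tr.channel_values):
            frames.append(
                pd.DataFrame(
                    {
                        "participant": tr.participant_id,
                        "group": tr.group_label,
                        "trial": tr.trial_index,
                        "channel": ch,
                        "time_s": np.round(time_s, 6),
                        "oxyhb": tr.channel_values[ch],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_long_tsv(
    path: str | Path,
    test_onset_s: float = 20.0,
    test_duration_s: float = 10.0,
    group_labels: Mapping[str, int] | None = None,
    sep: str = "\t",
) -> list[TrialRecord]:
    """Parse a long-form trial table into TrialRecords.

    ``group`` may be +1/-1 already or two string labels mapped through
    ``group_labels``. The test onset is located at ``test_onset_s``
    seconds into each trial's record (the protocol's baseline length).
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")

    def to_label(g) -> int:
        if group_labels is not None:
            return int(group_labels[str(g)])
        v = int(g)
        if v not in (-1, 1):
            raise ValueError(f"group must be +1/-1, got {v}")
        return v

    trials = []
    for (pid, trial), sub in df.groupby(["participant", "trial"], sort=True):
        values: dict[int, np.ndarray] = {}
        dt = None
        for ch, chunk in sub.groupby("channel"):
            chunk = chunk.sort_values("time_s")
            tvals = chunk["time_s"].to_numpy()
            if tvals.size > 1:
                step = float(np.median(np.diff(tvals)))
                if dt is None:
                    dt = step
            values[int(ch)] = chunk["oxyhb"].to_numpy(dtype=float)
        if dt is None:
            raise ValueError(f"trial {pid}/{trial} has too few samples")
        trials.append(
            TrialRecord(
                participant_id=str(pid),
                group_label=to_label(sub["group"].iloc[0]),
                trial_index=int(trial),
                channel_values=values,
                test_onset=int(round(test_onset_s / dt)),
                sampling_interval=dt,
                test_duration_s=test_duration_s,
            )
        )
    return trials


def write_features_tsv(ds: FeatureDataset, path: str | Path) -> None:
    data = {
        "participant": [p for p, _ in ds.provenance]
        if ds.provenance
        else [f"row{i}" for i in range(ds.n)],
        "trial": [t for _, t in ds.provenance]
        if ds.provenance
        else list(range(1, ds.n + 1)),
        "label": ds.t,
    }
    for j, ch in enumerate(ds.channel_ids):
        data[f"ch{ch}"] = ds.X[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_features_tsv(path: str | Path, sep: str = "\t") -> FeatureDataset:
    df = pd.read_csv(path, sep=sep)
    ch_cols = [c for c in df.columns if c.startswith("ch")]
    if not ch_cols:
        raise ValueError(f"no channel columns (ch<N>) in {path}")
    ids = tuple(int(c[2:]) for c in ch_cols)
    prov = tuple(
        (str(p), int(t)) for p, t in zip(df["participant"], df["trial"])
    )
    return FeatureDataset(
        df[ch_cols].to_numpy(dtype=float),
        df["label"].to_numpy(dtype=int),
        ids,
        prov,
    )


def load_config_file(path: str | Path) -> dict:
    """Read a YAML or JSON configuration file into a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
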