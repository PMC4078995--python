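"""Raw oxy-Hb time series -> per-trial mean Z-score feature matrix.

The preprocessing chain mirrors common practice in block-design fNIRS
studies: a zero-phase band-pass filter removes slow drift and cardiac
pulsation, each trial is standardized against a short pre-stimulus
baseline (making the relative NIRS units comparable across trials and
channels), and the classifier feature is the mean standardized response
over a post-onset analysis window placed to catch the delayed
hemodynamic peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

LEFT_CHANNELS: tuple[int, ...] = tuple(range(1, 13))
RIGHT_CHANNELS: tuple[int, ...] = tuple(range(13, 25))


@dataclass
class PreprocConfig:
    """Preprocessing parameters.

    Parameters
    ----------
    band_low, band_high
        Band-pass corner frequencies in Hz. The defaults (0.02-1.0 Hz)
        keep the hemodynamic response while rejecting drift below the
        low corner and heartbeat pulsation above the high corner.
    filter_order
        Butterworth order of the band-pass prototype; applied
        forward-backward, so the effective attenuation is doubled and
        the phase is zero.
    zscore_baseline_s
        Length, in seconds, of the pre-onset window whose mean and SD
        standardize the trial.
    feature_window_s
        ``(start, end)`` in seconds after test onset; the classifier
        feature is the mean Z-score over this closed interval.
    expected_channels
        Number of channels a complete trial must carry (ids
        ``1..expected_channels``).
    sd_ddof
        Delta degrees of freedom for the baseline SD (0 = population SD).
    """

    band_low: float = 0.02
    band_high: float = 1.0
    filter_order: int = 3
    zscore_baseline_s: float = 3.0
    feature_window_s: tuple[float, float] = (3.0, 10.0)
    expected_channels: int = 24
    sd_ddof: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        lo, hi = self.feature_window_s
        if not 0 <= lo < hi:
            raise ValueError("feature window must satisfy 0 <= start < end")
        if self.expected_channels < 1:
            raise ValueError("expected_channels must be >= 1")

    @property
    def expected_channel_ids(self) -> frozenset[int]:
        return frozenset(range(1, self.expected_channels + 1))


@dataclass
class TrialRecord:
    """One trial's multichannel concentration record.

    ``channel_values`` maps channel id -> sampled oxy-Hb concentration
    (relative units, mM*mm). ``test_onset`` is the sample index where
    the test period starts; everything before it is baseline fixation.
    Missing samples are encoded as NaN.
    """

    participant_id: str
    group_label: int
    trial_index: int
    channel_values: dict[int, np.ndarray]
    test_onset: int
    sampling_interval: float = 0.1
    test_duration_s: float = 10.0

    def __post_init__(self) -> None:
        if self.group_label not in (-1, +1):
            raise ValueError("group_label must be +1 or -1")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        self.channel_values = {
            int(c): np.asarray(v, dtype=float)
            for c, v in self.channel_values.items()
        }
        lengths = {v.size for v in self.channel_values.values()}
        if len(lengths) > 1:
            raise ValueError("all channel series must have equal length")

    @property
    def channels_present(self) -> frozenset[int]:
        return frozenset(self.channel_values)

    @property
    def n_samples(self) -> int:
        return next(iter(self.channel_values.values())).size


@dataclass
class ZScoredTrial:
    """Per-channel Z-score series, onset-relative.

    ``time_s[j]`` is the time of sample ``j`` relative to test onset
    (negative during the tail of the baseline); ``z[ch]`` are the
    standardized values on that grid.
    """

    time_s: np.ndarray
    z: dict[int, np.ndarray]
    trial: TrialRecord | None = None


@dataclass
class FeatureDataset:
    """N x D matrix of mean Z-scores with +/-1 labels.

    Rows are trials (the classification unit), columns are channels in
    ``channel_ids`` order. ``provenance`` carries ``(participant, trial)``
    per row so results can be traced back and rows regrouped by
    participant.
    """

    X: np.ndarray
    t: np.ndarray
    channel_ids: tuple[int, ...]
    provenance: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.t = np.asarray(self.t, dtype=int)
        self.channel_ids = tuple(int(c) for c in self.channel_ids)
        if self.X.shape[0] != self.t.size:
            raise ValueError("X rows and labels disagree")
        if self.X.shape[1] != len(self.channel_ids):
            raise ValueError("X columns and channel_ids disagree")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite entries")
        if not np.all(np.isin(self.t, (-1, 1))):
            raise ValueError("labels must be +1/-1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def restrict(self, channels: str | Sequence[int]) -> "FeatureDataset":
        """Return a copy restricted to a channel set.

        ``channels`` is ``"all"``, ``"left"`` (ids 1-12), ``"right"``
        (ids 13-24), or an explicit id sequence.
        """
        ids = resolve_channels(channels, self.channel_ids)
        cols = [self.channel_ids.index(c) for c in ids]
        return FeatureDataset(
            self.X[:, cols], self.t, ids, self.provenance
        )


def resolve_channels(
    channels: str | Sequence[int], available: Sequence[int]
) -> tuple[int, ...]:
    if isinstance(channels, str):
        key = channels.lower()
        if key in ("all", "bilateral"):
            ids = tuple(available)
        elif key == "left":
            ids = tuple(c for c in available if c in LEFT_CHANNELS)
        elif key == "right":
            ids = tuple(c for c in available if c in RIGHT_CHANNELS)
        else:
            raise ValueError(f"unknown channel set {channels!r}")
    else:
        ids = tuple(int(c) for c in channels)
    missing = [c for c in ids if c not in available]
    if missing:
        raise ValueError(f"channels not in dataset: {missing}")
    if not ids:
        raise ValueError("empty channel selection")
    return ids


def bandpass_filter(
    series: np.ndarray, cfg: PreprocConfig, sampling_interval: float
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of one channel's series.

    Forward-backward application (``sosfiltfilt``) doubles the effective
    order and cancels phase distortion, so event timing relative to the
    stimulus is preserved.
    """
    x = np.asarray(series, dtype=float)
    fs = 1.0 / sampling_interval
    nyq = fs / 2.0
    if cfg.band_high >= nyq:
        raise ValueError(
            f"band_high={cfg.band_high} Hz must be below Nyquist {nyq} Hz"
        )
    sos = signal.butter(
        cfg.filter_order,
        (cfg.band_low, cfg.band_high),
        btype="bandpass",
        fs=fs,
        output="sos",
    )
    # sosfiltfilt needs padlen < n; give a clear error for short records
    min_len = 3 * (2 * sos.shape[0] + 1)
    if x.size <= min_len:
        raise ValueError(
            f"series of length {x.size} too short for stable filtering; "
            f"need more than {min_len} samples"
        )
    # the slow corner's impulse response is long (~1/band_low s); pad by
    # ~3 time constants so startup transients decay inside the pad. Even
    # (mirror) padding: point reflection injects a DC jump of twice the
    # endpoint-to-local-mean offset, which the slow corner rings on.
    padlen = min(x.size - 1, max(min_len, int(round(3.0 * fs / cfg.band_low))))
    return signal.sosfiltfilt(sos, x, padlen=padlen, padtype="even")


def zscore_trial(
    trial: TrialRecord, cfg: PreprocConfig, *, prefiltered: bool = False
) -> ZScoredTrial:
    """Standardize one trial against its pre-onset baseline.

    Each channel is band-pass filtered (unless ``prefiltered``), then
    every sample from ``zscore_baseline_s`` seconds before onset through
    the test offset is mapped to ``(x - m) / s`` where ``m`` and ``s``
    are the mean and SD of the filtered values in the baseline window
    immediately preceding onset.
    """
    dt = trial.sampling_interval
    n_base = int(round(cfg.zscore_baseline_s / dt))
    if trial.test_onset < n_base:
        raise ValueError(
            f"baseline window needs {n_base} samples before onset, "
            f"trial has {trial.test_onset}"
        )
    n_test = int(round(trial.test_duration_s / dt))
    stop = min(trial.test_onset + n_test + 1, trial.n_samples)
    start = trial.test_onset - n_base
    time_s = (np.arange(start, stop) - trial.test_onset) * dt

    z: dict[int, np.ndarray] = {}
    for ch in sorted(trial.channel_values):
        raw = trial.channel_values[ch]
        filt = raw if prefiltered else bandpass_filter(raw, cfg, dt)
        base = filt[start : trial.test_onset]
        m = float(np.mean(base))
        s = float(np.std(base, ddof=cfg.sd_ddof))
        if not s > 0:
            raise ValueError(f"zero baseline SD on channel {ch}")
        z[ch] = (filt[start:stop] - m) / s
    return ZScoredTrial(time_s=time_s, z=z, trial=trial)


def extract_feature(ztrial: ZScoredTrial, cfg: PreprocConfig) -> np.ndarray:
    """Mean Z-score per channel over the analysis window.

    The window is the closed interval ``feature_window_s`` in
    onset-relative seconds; samples landing exactly on either endpoint
    are included.
    """
    lo, hi = cfg.feature_window_s
    eps = 1e-9
    mask = (ztrial.time_s >= lo - eps) & (ztrial.time_s <= hi + eps)
    if not mask.any():
        raise ValueError("feature window contains no samples")
    chans = sorted(ztrial.z)
    return np.array([float(np.mean(ztrial.z[ch][mask])) for ch in chans])


def qc_reject_trials(
    trials: Iterable[TrialRecord], cfg: PreprocConfig
) -> tuple[list[TrialRecord], list[str]]:
    """Keep only trials with every expected channel completely recorded.

    A trial is retained iff its channel set equals the full expected set
    and no channel contains a missing-sample sentinel (NaN). The log
    holds one line per rejected trial with the reason.
    """
    expected = cfg.expected_channel_ids
    retained: list[TrialRecord] = []
    log: list[str] = []
    for tr in trials:
        tag = f"participant={tr.participant_id} trial={tr.trial_index}"
        if tr.channels_present != expected:
            diff = sorted(expected - tr.channels_present) or sorted(
                tr.channels_present - expected
            )
            log.append(f"{tag}: rejected, channel set mismatch {diff}")
            continue
        gappy = [
            ch
            for ch in sorted(tr.channel_values)
            if np.isnan(tr.channel_values[ch]).any()
        ]
        if gappy:
            log.append(f"{tag}: rejected, missing samples in channels {gappy}")
            continue
        retained.append(tr)
    if not retained:
        log.append("warning: no trials retained")
    return retained, log


def build_dataset(
    trials: Sequence[TrialRecord],
    cfg: PreprocConfig | None = None,
    channels: str | Sequence[int] = "all",
) -> tuple[FeatureDataset, list[str]]:
    """Full preprocessing chain: QC -> filter -> Z-score -> window mean.

    Returns the feature dataset (one row per retained trial) and the QC
    rejection log. ``channels`` restricts the columns to a hemisphere or
    an explicit id list after feature extraction.
    """
    cfg = cfg or PreprocConfig()
    retained, log = qc_reject_trials(trials, cfg)
    if not retained:
        raise ValueError("no trials retained after QC")
    intervals = {tr.sampling_interval for tr in retained}
    if len(intervals) > 1:
        raise ValueError(f"mixed sampling intervals: {sorted(intervals)}")

    rows, labels, prov = [], [], []
    channel_ids: tuple[int, ...] | None = None
    for tr in retained:
        zt = zscore_trial(tr, cfg)
        ids = tuple(sorted(zt.z))
        if channel_ids is None:
            channel_ids = ids
        elif ids != channel_ids:
            raise ValueError("inconsistent channel sets across retained trials")
        rows.append(extract_feature(zt, cfg))
        labels.append(tr.group_label)
        prov.append((tr.participant_id, tr.trial_index))

    ds = FeatureDataset(
        np.vstack(rows), np.array(labels), channel_ids, tuple(prov)
    )
    if channels != "all":
        ds = ds.restrict(channels)
    return ds, log
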