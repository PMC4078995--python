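"""Synthetic multichannel fNIRS studies with known ground truth.

Two generators share one study specification. The time-series
generator emulates the raw signal a continuous-wave NIRS device
records during a block-design trial — slow drift, cardiac pulsation,
white sensor noise, and (on informative channels of one group) a
gamma-shaped hemodynamic response during the test period — so the full
preprocessing chain can be exercised. The feature-level generator
draws the mean Z-score features directly from group-shifted
multivariate normals, which is orders of magnitude faster when only
the classification and screening stages are under study.

Effect sizes are specified in units of the across-trial SD of the
feature, so "a +1.5 effect on channel 15" means the two groups' mean
features at channel 15 differ by 1.5 feature-SDs — the scale on which
classifier recovery and t-test power are naturally stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import (
    FeatureDataset,
    PreprocConfig,
    TrialRecord,
    bandpass_filter,
)


@dataclass
class SyntheticSpec:
    """Study-shape and signal parameters of a synthetic experiment.

    ``informative`` maps channel id -> signed effect size (in feature-SD
    units); positive effects raise the +1 group's response, negative
    effects lower it. Amplitudes are in the same arbitrary
    concentration units as the raw series; frequencies in Hz.
    """

    n_trials_per_group: int = 25
    n_channels: int = 24
    informative: dict[int, float] = field(default_factory=dict)
    sampling_interval: float = 0.1
    baseline_s: float = 20.0
    test_s: float = 10.0
    hrf_peak_s: float = 5.5
    hrf_shape: float = 4.0
    noise_sd: float = 1.0
    heartbeat_amp: float = 0.4
    heartbeat_freq: float = 1.1
    drift_amp: float = 1.0
    drift_freq: float = 0.008
    dropout_rate: float = 0.0
    equicorrelation: float = 0.0

    def __post_init__(self) -> None:
        bad = [c for c in self.informative if not 1 <= c <= self.n_channels]
        if bad:
            raise ValueError(f"informative channels outside array: {bad}")
        for name in ("noise_sd", "heartbeat_amp", "drift_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.baseline_s < 20.0:
            raise ValueError("baseline period must be at least 20 s")


@dataclass
class GroundTruth:
    informative: dict[int, float]
    expected_optimal: tuple[int, ...]
    group_of_trial: np.ndarray
    dropped_trials: tuple[int, ...] = ()


def paperlike50x24() -> SyntheticSpec:
    """The default study shape: 25+25 trials, 24 channels, seven
    informative channels (+/-1.5 feature-SD) split across hemispheres."""
    return SyntheticSpec(
        informative={
            15: +1.5, 16: +1.5, 18: -1.5,
            3: +1.5, 5: +1.5, 6: -1.5, 14: +1.5,
        }
    )


PRESETS = {"paperlike50x24": paperlike50x24}


def hemodynamic_response(
    time_s: np.ndarray | float, peak_s: float = 5.5, amplitude: float = 1.0,
    shape: float = 4.0,
) -> np.ndarray | float:
    """Normalized gamma-family response curve.

    Zero at t = 0, unimodal with maximum ``amplitude`` exactly at
    ``peak_s``, decaying back toward zero — the canonical shape of the
    oxy-Hb response whose peak lags stimulus onset by a few seconds.
    """
    if peak_s <= 0:
        raise ValueError("peak_s must be positive")
    t = np.asarray(time_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    r = t / peak_s
    with np.errstate(divide="ignore"):
        out = amplitude * np.power(r, shape) * np.exp(shape * (1.0 - r))
    return out if out.ndim else float(out)


def _trial_noise(
    rng: np.random.Generator, spec: SyntheticSpec, n: int, time: np.ndarray
) -> np.ndarray:
    drift = spec.drift_amp * np.sin(
        2 * np.pi * spec.drift_freq * time + rng.uniform(0, 2 * np.pi)
    )
    heart = spec.heartbeat_amp * np.sin(
        2 * np.pi * spec.heartbeat_freq * time + rng.uniform(0, 2 * np.pi)
    )
    return drift + heart + rng.normal(0.0, spec.noise_sd, size=n)


def _calibrate_gain(
    spec: SyntheticSpec, cfg: PreprocConfig, seed: int, n_pilot: int = 60
) -> tuple[float, float]:
    """Empirical (feature SD, feature shift per unit HRF amplitude).

    The Z-transform divides by each trial's baseline SD, so the feature
    shift produced by a given HRF amplitude depends on the noise
    settings; a pilot batch of null trials measures both the null
    feature SD and the realized per-unit shift, and the generator scales
    amplitudes accordingly.
    """
    rng = np.random.default_rng(seed)
    dt = spec.sampling_interval
    n = int(round((spec.baseline_s + spec.test_s) / dt)) + 1
    time = np.arange(n) * dt
    onset = int(round(spec.baseline_s / dt))
    hrf = np.zeros(n)
    tt = time[onset:] - time[onset]
    hrf[onset:] = hemodynamic_response(tt, spec.hrf_peak_s, 1.0, spec.hrf_shape)

    n_base = int(round(cfg.zscore_baseline_s / dt))
    lo, hi = cfg.feature_window_s
    feats, shifts = [], []
    for _ in range(n_pilot):
        noise = _trial_noise(rng, spec, n, time)
        for sig in (noise, noise + hrf):
            filt = bandpass_filter(sig, cfg, dt)
            base = filt[onset - n_base : onset]
            m, s = float(np.mean(base)), float(np.std(base, ddof=cfg.sd_ddof))
            rel = time - time[onset]
            mask = (rel >= lo - 1e-9) & (rel <= hi + 1e-9)
            f = float(np.mean((filt[mask] - m) / s))
            if sig is noise:
                feats.append(f)
            else:
                shifts.append(f - feats[-1])
    sd = float(np.std(feats, ddof=1))
    gain = float(np.mean(shifts))
    if not gain > 0:
        raise RuntimeError("HRF gain calibration failed")
    return sd, gain


def generate_timeseries_study(
    spec: SyntheticSpec,
    seed: int,
    cfg: PreprocConfig | None = None,
) -> tuple[list[TrialRecord], GroundTruth]:
    """Raw-trial generator: one TrialRecord per trial, both groups.

    Informative channels add a signed hemodynamic response to the +1
    group's test period, with amplitude calibrated so the realized
    group difference in the mean-Z feature approximates the requested
    effect (in feature-SD units). ``dropout_rate`` marks one random
    channel NaN in that fraction of trials, to exercise QC rejection.
    """
    cfg = cfg or PreprocConfig(expected_channels=spec.n_channels)
    rng = np.random.default_rng(seed)
    sd_f, gain = _calibrate_gain(spec, cfg, seed=(seed * 9973 + 17) % (2**31))

    dt = spec.sampling_interval
    n = int(round((spec.baseline_s + spec.test_s) / dt)) + 1
    time = np.arange(n) * dt
    onset = int(round(spec.baseline_s / dt))
    hrf_unit = np.zeros(n)
    tt = time[onset:] - time[onset]
    hrf_unit[onset:] = hemodynamic_response(
        tt, spec.hrf_peak_s, 1.0, spec.hrf_shape
    )

    n_total = 2 * spec.n_trials_per_group
    groups = np.array(
        [+1] * spec.n_trials_per_group + [-1] * spec.n_trials_per_group
    )
    drop_mask = rng.random(n_total) < spec.dropout_rate

    trials: list[TrialRecord] = []
    dropped: list[int] = []
    for i in range(n_total):
        values: dict[int, np.ndarray] = {}
        for ch in range(1, spec.n_channels + 1):
            sig = _trial_noise(rng, spec, n, time)
            effect = spec.informative.get(ch, 0.0)
            if effect and groups[i] == +1:
                amp = effect * sd_f / gain
                sig = sig + amp * hrf_unit
            values[ch] = sig
        if drop_mask[i]:
            victim = int(rng.integers(1, spec.n_channels + 1))
            values[victim] = values[victim].copy()
            values[victim][onset : onset + 5] = np.nan
            dropped.append(i)
        pid = f"P{(i % spec.n_trials_per_group) + 1:02d}{'A' if groups[i] > 0 else 'B'}"
        trials.append(
            TrialRecord(
                participant_id=pid,
                group_label=int(groups[i]),
                trial_index=i + 1,
                channel_values=values,
                test_onset=onset,
                sampling_interval=dt,
                test_duration_s=spec.test_s,
            )
        )
    truth = GroundTruth(
        informative=dict(spec.informative),
        expected_optimal=tuple(sorted(spec.informative)),
        group_of_trial=groups,
        dropped_trials=tuple(dropped),
    )
    return trials, truth


def generate_feature_study(
    spec: SyntheticSpec, seed: int
) -> tuple[FeatureDataset, GroundTruth]:
    """Feature-level generator: draw mean-Z features directly.

    Each group's features are multivariate normal with unit variances
    and optional equicorrelation; the +1 group's mean is shifted by the
    informative effects. Bypasses the time-series stage for fast
    statistical studies.
    """
    rng = np.random.default_rng(seed)
    D = spec.n_channels
    rho = spec.equicorrelation
    if not -1.0 / max(D - 1, 1) < rho < 1.0:
        raise ValueError(
            f"equicorrelation {rho} makes the covariance non-positive-definite"
        )
    cov = np.full((D, D), rho)
    np.fill_diagonal(cov, 1.0)
    shift = np.zeros(D)
    for ch, eff in spec.informative.items():
        shift[ch - 1] = eff

    npg = spec.n_trials_per_group
    Xa = rng.multivariate_normal(shift, cov, size=npg, method="cholesky")
    Xb = rng.multivariate_normal(np.zeros(D), cov, size=npg, method="cholesky")
    X = np.vstack([Xa, Xb])
    t = np.array([+1] * npg + [-1] * npg)
    prov = tuple(
        (f"S{i + 1:02d}{'A' if lab > 0 else 'B'}", i + 1)
        for i, lab in enumerate(t)
    )
    ds = FeatureDataset(X, t, tuple(range(1, D + 1)), prov)
    truth = GroundTruth(
        informative=dict(spec.informative),
        expected_optimal=tuple(sorted(spec.informative)),
        group_of_trial=t,
    )
    return ds, truth
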