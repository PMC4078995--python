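"""Preprocessing chain: band-pass filter, baseline Z-score, window mean, QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsweep import (
    PreprocConfig,
    TrialRecord,
    bandpass_filter,
    build_dataset,
    extract_feature,
    qc_reject_trials,
    zscore_trial,
)
from nirsweep.preprocess import ZScoredTrial

FS = 10.0
DT = 1.0 / FS


def sine(freq, duration_s, amp=1.0):
    t = np.arange(0, duration_s, DT)
    return t, amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_constant_series_is_pure_dc_and_rejected(self):
        out = bandpass_filter(np.full(400, 5.0), PreprocConfig(), DT)
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_passband_amplitude_preserved(self):
        _, x = sine(0.1, 300.0)
        y = bandpass_filter(x, PreprocConfig(), DT)
        mid = slice(300, -300)  # avoid edge transients
        assert np.max(np.abs(y[mid])) == pytest.approx(1.0, rel=0.05)

    def test_stopband_heartbeat_attenuated(self):
        # steady-state gain (edges carry the filter's startup transient)
        _, x = sine(2.5, 300.0)
        y = bandpass_filter(x, PreprocConfig(), DT)
        assert np.max(np.abs(y[300:-300])) < 0.10
        assert np.max(np.abs(y)) < 0.30  # edge transients stay bounded

    def test_deep_stopband_attenuation(self):
        # >= 20 dB down at 3 Hz and at ~DC for 10 Hz sampling
        _, x = sine(3.0, 300.0)
        y = bandpass_filter(x, PreprocConfig(), DT)
        assert np.max(np.abs(y[300:-300])) < 0.1  # -20 dB
        _, x = sine(0.001, 3000.0)
        y = bandpass_filter(x, PreprocConfig(), DT)
        assert np.max(np.abs(y[3000:-3000])) < 0.1

    def test_passband_idempotence(self):
        _, x = sine(0.1, 300.0)
        once = bandpass_filter(x, PreprocConfig(), DT)
        twice = bandpass_filter(once, PreprocConfig(), DT)
        mid = slice(300, -300)
        ratio = np.max(np.abs(twice[mid])) / np.max(np.abs(once[mid]))
        assert abs(ratio - 1.0) < 0.10

    def test_too_short_series_names_minimum(self):
        with pytest.raises(ValueError, match="samples"):
            bandpass_filter(np.zeros(10), PreprocConfig(), DT)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(np.zeros(400), PreprocConfig(band_high=6.0), DT)


def _trial(values_by_channel, onset, dt=DT, label=1):
    return TrialRecord(
        participant_id="p1",
        group_label=label,
        trial_index=1,
        channel_values=values_by_channel,
        test_onset=onset,
        sampling_interval=dt,
    )


class TestZScore:
    cfg = PreprocConfig(zscore_baseline_s=0.4, feature_window_s=(0.1, 0.3))

    def test_hand_computed_example(self):
        # baseline {1,1,3,3}: mean 2, population SD 1 -> test sample 4 -> d=2
        series = np.array([1.0, 1.0, 3.0, 3.0, 4.0, 4.0])
        zt = zscore_trial(
            _trial({1: series}, onset=4), self.cfg, prefiltered=True
        )
        assert zt.z[1][-1] == pytest.approx(2.0)

    def test_zero_numerator_gives_zero(self):
        series = np.array([1.0, 3.0, 1.0, 3.0, 2.0, 2.0])
        zt = zscore_trial(
            _trial({1: series}, onset=4), self.cfg, prefiltered=True
        )
        assert zt.z[1][-1] == pytest.approx(0.0)
        assert zt.z[1][-2] == pytest.approx(0.0)

    def test_sample_sd_convention_configurable(self):
        cfg = PreprocConfig(
            zscore_baseline_s=0.4, feature_window_s=(0.1, 0.3), sd_ddof=1
        )
        series = np.array([1.0, 1.0, 3.0, 3.0, 4.0, 4.0])
        zt = zscore_trial(_trial({1: series}, onset=4), cfg, prefiltered=True)
        sd = np.std([1, 1, 3, 3], ddof=1)
        assert zt.z[1][-1] == pytest.approx(2.0 / sd)

    def test_zero_baseline_sd_names_channel(self):
        series = np.array([2.0, 2.0, 2.0, 2.0, 4.0])
        with pytest.raises(ValueError, match="channel 1"):
            zscore_trial(_trial({1: series}, onset=4), self.cfg, prefiltered=True)

    def test_baseline_shorter_than_config_errors(self):
        series = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="baseline"):
            zscore_trial(_trial({1: series}, onset=2), self.cfg, prefiltered=True)

    @given(
        a=st.floats(min_value=0.05, max_value=50.0),
        c=st.floats(min_value=-100.0, max_value=100.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, c):
        # Z-scoring is invariant under x -> a*x + c (a > 0), filter included
        rng = np.random.default_rng(3)
        x = rng.normal(size=400) + 0.5 * np.sin(
            2 * np.pi * 0.2 * np.arange(400) * DT
        )
        cfg = PreprocConfig()
        z1 = zscore_trial(_trial({1: x}, onset=300), cfg)
        z2 = zscore_trial(_trial({1: a * x + c}, onset=300), cfg)
        np.testing.assert_allclose(z1.z[1], z2.z[1], atol=1e-8)

    def test_z_series_spans_3s_before_onset_to_offset(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=400)
        zt = zscore_trial(_trial({1: x}, onset=250), PreprocConfig())
        assert zt.time_s[0] == pytest.approx(-3.0)
        assert zt.time_s[-1] <= 10.0 + 1e-9


class TestExtractFeature:
    def test_constant_window(self):
        time = np.arange(-30, 101) * DT
        zt = ZScoredTrial(time, {1: np.full(time.size, 1.5)})
        assert extract_feature(zt, PreprocConfig())[0] == pytest.approx(1.5)

    def test_linear_ramp_matches_bruteforce_mean(self):
        # Z ramps 0 -> 7 over 0..10 s; oracle = plain average of included samples
        time = np.arange(0, 101) * DT
        z = 0.7 * time
        zt = ZScoredTrial(time, {1: z})
        included = z[(time >= 3.0) & (time <= 10.0)]
        assert extract_feature(zt, PreprocConfig())[0] == pytest.approx(
            included.mean()
        )
        # closed interval: endpoints at exactly 3.0 and 10.0 s are in
        assert included.size == 71

    def test_single_sample_window(self):
        zt = ZScoredTrial(np.array([5.0]), {1: np.array([-2.0])})
        assert extract_feature(zt, PreprocConfig())[0] == pytest.approx(-2.0)

    def test_empty_window_errors(self):
        zt = ZScoredTrial(np.array([0.0, 1.0]), {1: np.array([1.0, 1.0])})
        with pytest.raises(ValueError, match="window"):
            extract_feature(zt, PreprocConfig())


def _full_trial(rng, n_channels=4, n=400, onset=300, pid="p1", idx=1, label=1):
    return TrialRecord(
        participant_id=pid,
        group_label=label,
        trial_index=idx,
        channel_values={c: rng.normal(size=n) for c in range(1, n_channels + 1)},
        test_onset=onset,
        sampling_interval=DT,
    )


class TestQC:
    cfg = PreprocConfig(expected_channels=4)

    def test_missing_channel_rejected(self):
        rng = np.random.default_rng(0)
        tr = _full_trial(rng)
        del tr.channel_values[3]
        retained, log = qc_reject_trials([tr], self.cfg)
        assert retained == [] and "mismatch" in log[0]

    def test_complete_trial_retained(self):
        rng = np.random.default_rng(0)
        retained, _ = qc_reject_trials([_full_trial(rng)], self.cfg)
        assert len(retained) == 1

    def test_gap_marker_rejects_and_counts(self):
        rng = np.random.default_rng(0)
        trials = [_full_trial(rng, idx=i) for i in range(1, 6)]
        for i in (1, 3):
            trials[i].channel_values[2][100] = np.nan
        retained, log = qc_reject_trials(trials, self.cfg)
        assert len(retained) == 3
        assert sum("missing samples" in line for line in log) == 2

    @given(st.integers(min_value=0, max_value=6))
    @settings(max_examples=10, deadline=None)
    def test_retained_plus_rejected_equals_input(self, n_bad):
        rng = np.random.default_rng(n_bad)
        trials = [_full_trial(rng, idx=i) for i in range(6)]
        for i in range(n_bad):
            trials[i].channel_values[1][0] = np.nan
        retained, log = qc_reject_trials(trials, self.cfg)
        n_rejected = sum("rejected" in line for line in log)
        assert len(retained) + n_rejected == 6


class TestBuildDataset:
    def test_shapes_and_restriction(self):
        rng = np.random.default_rng(5)
        trials = [
            _full_trial(rng, n_channels=24, pid=f"p{i}", idx=i, label=lab)
            for i, lab in enumerate([1] * 3 + [-1] * 3)
        ]
        ds, _ = build_dataset(trials, PreprocConfig())
        assert ds.X.shape == (6, 24)
        right, _ = build_dataset(trials, PreprocConfig(), channels="right")
        assert right.X.shape == (6, 12)
        assert right.channel_ids == tuple(range(13, 25))

    def test_single_trial_is_row_matrix(self):
        rng = np.random.default_rng(6)
        cfg = PreprocConfig(expected_channels=4)
        ds, _ = build_dataset([_full_trial(rng)], cfg)
        assert ds.X.shape == (1, 4)

    def test_mixed_sampling_intervals_error(self):
        rng = np.random.default_rng(7)
        t1, t2 = _full_trial(rng, idx=1), _full_trial(rng, idx=2)
        t2.sampling_interval = 0.2
        with pytest.raises(ValueError, match="sampling"):
            build_dataset([t1, t2], PreprocConfig(expected_channels=4))

    def test_channel_permutation_permutes_columns(self):
        rng = np.random.default_rng(8)
        tr = _full_trial(rng)
        perm = {1: 3, 2: 1, 3: 4, 4: 2}
        tr2 = TrialRecord(
            participant_id="p1",
            group_label=1,
            trial_index=1,
            channel_values={perm[c]: v.copy() for c, v in tr.channel_values.items()},
            test_onset=tr.test_onset,
            sampling_interval=DT,
        )
        cfg = PreprocConfig(expected_channels=4)
        ds1, _ = build_dataset([tr], cfg)
        ds2, _ = build_dataset([tr2], cfg)
        for old, new in perm.items():
            j1 = ds1.channel_ids.index(old)
            j2 = ds2.channel_ids.index(new)
            assert ds1.X[0, j1] == pytest.approx(ds2.X[0, j2])
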