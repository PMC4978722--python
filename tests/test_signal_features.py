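"""Feature-extraction tests: burst rejection, windowing, filtering, power, PLV, AEP."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

import corticode as cc
from corticode import signal_features as sf
from corticode.synthetic_data import ConfigurationError

FS = 1000.0


def _ar1_noise(rng, shape, sd=40.0, a=0.95):
    drive = rng.standard_normal(shape) * sd * np.sqrt(1 - a * a)
    return sps.lfilter([1.0], [1.0, -a], drive, axis=-1)


class TestWindowedSd:
    def test_matches_brute_force_sliding_std(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        out = sf.windowed_sd(x, FS, win_ms=100)
        view = np.lib.stride_tricks.sliding_window_view(x, 100)
        expected = view.std(axis=-1)
        assert np.allclose(out[99:], expected, atol=1e-10)


class TestBurstThreshold:
    def test_zero_signal_gives_zero_threshold(self):
        data = np.zeros((4, 15000))
        assert sf.estimate_burst_threshold(data, FS) == 0.0

    def test_short_calibration_segment_rejected(self):
        with pytest.raises(ConfigurationError):
            sf.estimate_burst_threshold(np.zeros((2, 5000)), FS)

    def test_white_noise_threshold_matches_monte_carlo_oracle(self):
        """mean + 3 SD of 100-sample SD statistics, against an independent MC estimate."""
        sigma = 25.0
        rng = np.random.default_rng(1)
        data = rng.standard_normal((8, 60000)) * sigma
        thr = sf.estimate_burst_threshold(data, FS, calibration_s=60.0)
        # oracle: independent draws of 100-sample windows
        draws = rng.standard_normal((20000, 100)) * sigma
        sds = draws.std(axis=1)
        oracle = sds.mean() + 3 * sds.std()
        assert thr == pytest.approx(oracle, rel=0.05)

    def test_threshold_exceeds_nonburst_sd_p99_with_bursts_present(self):
        """With ~10% burst occupancy the threshold clears the non-burst SD distribution."""
        rng = np.random.default_rng(2)
        data = _ar1_noise(rng, (30, 60000))
        burst_cols = np.zeros(60000, dtype=bool)
        t = 2000
        while t < 58000:
            data[:, t:t + 600] *= 6.0
            burst_cols[t:t + 600] = True
            t += 6000
        thr = sf.estimate_burst_threshold(data, FS, calibration_s=60.0)
        clean_sds = sf.windowed_sd(data[:, ~burst_cols], FS, win_ms=100)[:, 100:]
        assert thr > np.percentile(clean_sds, 99)


class TestDetectBursts:
    def test_zero_signal_empty_mask(self):
        mask = sf.detect_bursts(np.zeros((30, 20000)), threshold_uv=5.0, fs_hz=FS)
        assert not mask.mask.any()

    @pytest.mark.parametrize(
        "dur_ms,n_chan,expect_detection",
        [(200, 30, True), (100, 30, False), (200, 20, False)],
        ids=["200ms-30ch", "100ms-too-short", "20ch-below-site-count"],
    )
    def test_injected_burst_detection_rules(self, dur_ms, n_chan, expect_detection):
        """>24 sites above threshold and >=150 ms duration are both required."""
        rng = np.random.default_rng(3)
        data = _ar1_noise(rng, (96, 130000))
        thr = sf.estimate_burst_threshold(data, FS, calibration_s=60.0)
        i0 = 90000
        i1 = i0 + dur_ms
        data[:n_chan, i0:i1] *= 10.0
        mask = sf.detect_bursts(data, thr, fs_hz=FS)
        intervals = mask.intervals()
        if expect_detection:
            assert len(intervals) == 1
            s, e = intervals[0]
            inj = (i0 / FS, i1 / FS)
            inter = max(0.0, min(e, inj[1]) - max(s, inj[0]))
            union = max(e, inj[1]) - min(s, inj[0])
            assert inter / union > 0.5
        else:
            assert not intervals

    def test_mask_runs_respect_min_duration(self):
        rng = np.random.default_rng(4)
        data = _ar1_noise(rng, (96, 130000))
        thr = sf.estimate_burst_threshold(data, FS)
        for start in (70000, 90000, 110000):
            data[:40, start:start + 400] *= 8.0
        mask = sf.detect_bursts(data, thr, fs_hz=FS)
        for s, e in mask.intervals():
            assert (e - s) >= 0.150

    def test_detector_idempotent_after_burst_replacement(self):
        """Replacing burst samples with fresh background yields an empty mask."""
        rng = np.random.default_rng(5)
        data = _ar1_noise(rng, (96, 130000))
        thr = sf.estimate_burst_threshold(data, FS)
        data[:50, 80000:80500] *= 8.0
        mask = sf.detect_bursts(data, thr, fs_hz=FS)
        assert mask.mask.any()
        clean = data.copy()
        clean[:, mask.mask] = _ar1_noise(rng, (96, int(mask.mask.sum())))
        mask2 = sf.detect_bursts(clean, thr, fs_hz=FS)
        assert not mask2.mask.any()


class TestExtractWindows:
    def test_one_trial_yields_28_periods_per_condition(self, site_map):
        sched = cc.generate_long_tone_protocol([22000.0], repeats=1, seed=1)
        rec = cc.simulate_lfp_session(
            site_map, sched,
            effects=cc.LfpEffects(sustained_amplitude_uv=0.0), seed=1,
        )
        windows = sf.extract_windows(rec, None, length_ms=1000)
        sound = [w for w in windows if w.condition == "sound"]
        spont = [w for w in windows if w.condition == "spontaneous"]
        assert len(sound) == 28 and len(spont) == 28

    def test_windows_start_at_period_beginnings(self, null_long_tone_recording):
        windows = sf.extract_windows(null_long_tone_recording, None, length_ms=200)
        for w in windows:
            rel = (w.start_s - 1.0) % 1.0  # period grid: 1 s steps from align+1 s
            assert rel == pytest.approx(0.0, abs=1e-9) or rel == pytest.approx(1.0, abs=1e-9)
            assert w.length_ms == 200

    def test_burst_overlapping_periods_removed_exactly(self, null_long_tone_recording):
        """A mask covering 2-5 s post-onset removes exactly 3 sound periods (brute force)."""
        rec = null_long_tone_recording
        onset = rec.schedule.events["onset_s"].iloc[0]
        mask_vec = np.zeros(rec.n_samples, dtype=bool)
        mask_vec[int((onset + 2.0) * FS): int((onset + 5.0) * FS)] = True
        mask = sf.BurstMask(mask=mask_vec, threshold_uv=1.0, fs_hz=FS)
        full = sf.extract_windows(rec, None, length_ms=1000)
        masked = sf.extract_windows(rec, mask, length_ms=1000)
        removed = {
            (w.trial_id, w.condition, w.start_s) for w in full
        } - {(w.trial_id, w.condition, w.start_s) for w in masked}
        # brute-force expectation: sound periods starting at onset+2, +3, +4
        assert removed == {(0, "sound", onset + 2.0), (0, "sound", onset + 3.0), (0, "sound", onset + 4.0)}

    def test_subsampling_balances_labels(self, long_tone_recording):
        windows = sf.extract_windows(long_tone_recording, None, length_ms=1000,
                                     samples_per_label=20, seed=3)
        from collections import Counter

        counts = Counter((w.frequency_hz, w.condition) for w in windows)
        assert set(counts.values()) == {20}

    def test_invalid_window_length_rejected(self, null_long_tone_recording):
        with pytest.raises(ConfigurationError):
            sf.extract_windows(null_long_tone_recording, None, length_ms=300)


class TestBandpass:
    def test_in_band_sinusoid_amplitude_preserved(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 70.0 * t)
        y = sf.bandpass(x, "high_gamma", FS)
        assert np.abs(y[500:1500]).max() == pytest.approx(1.0, rel=0.02)

    def test_out_of_band_sinusoid_suppressed(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = sf.bandpass(x, "high_gamma", FS)
        assert np.abs(y[500:1500]).max() < 0.01

    def test_measured_corner_frequencies(self):
        """Empirical -3 dB corners of the net response within 10% of (60, 80) Hz."""
        freqs = np.arange(40.0, 100.0, 1.0)
        gains = []
        t = np.arange(4000) / FS
        for f in freqs:
            x = np.sin(2 * np.pi * f * t)
            y = sf.bandpass(x, "high_gamma", FS)
            gains.append(np.abs(y[1000:3000]).max())
        gains = np.asarray(gains)
        above = gains >= (1 / np.sqrt(2))
        lo_corner = freqs[above][0]
        hi_corner = freqs[above][-1]
        assert abs(lo_corner - 60.0) / 60.0 < 0.10
        assert abs(hi_corner - 80.0) / 80.0 < 0.10

    def test_short_segment_rejected(self):
        with pytest.raises(ConfigurationError):
            sf.bandpass(np.zeros(10), "theta", FS)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            sf.bandpass(np.zeros(1000), (100.0, 600.0), FS)


class TestBandPower:
    def test_zero_signal(self):
        assert sf.band_power(np.zeros(1000), "high_gamma", FS) == 0.0

    def test_in_band_sinusoid_rms(self):
        t = np.arange(1000) / FS
        x = 3.0 * np.sin(2 * np.pi * 70.0 * t)
        assert sf.band_power(x, "high_gamma", FS) == pytest.approx(3.0 / np.sqrt(2), rel=0.02)

    def test_white_noise_matches_filter_response_oracle(self):
        """E[RMS^2] equals sigma^2 x mean net power gain of the filter (Parseval)."""
        sigma = 10.0
        sos = sps.butter(4, (60, 80), btype="bandpass", fs=FS, output="sos")
        w, h = sps.sosfreqz(sos, worN=4096, fs=FS)
        # forward-backward filtering squares the magnitude response
        expected_power = sigma**2 * np.mean(np.abs(h) ** 4)
        rng = np.random.default_rng(6)
        vals = [
            sf.band_power(rng.standard_normal(2000) * sigma, "high_gamma", FS) ** 2
            for _ in range(300)
        ]
        assert np.mean(vals) == pytest.approx(expected_power, rel=0.1)


class TestPlv:
    def test_constant_phase_difference_gives_unity(self):
        t = np.arange(1000) / FS  # 70 cycles exactly -> bin-aligned
        x = np.cos(2 * np.pi * 70.0 * t)
        y = np.cos(2 * np.pi * 70.0 * t - np.pi / 2)
        assert sf.plv(x, y, band=None) == pytest.approx(1.0, abs=1e-9)
        assert sf.plv(x, x, band="high_gamma") == pytest.approx(1.0, abs=1e-6)

    def test_band_filtered_delayed_copy_near_unity(self):
        t = np.arange(1000) / FS
        x = np.sin(2 * np.pi * 70.0 * t)
        y = np.sin(2 * np.pi * 70.0 * (t - 0.003))
        assert sf.plv(x, y, band="high_gamma") == pytest.approx(1.0, abs=1e-2)

    def test_independent_noise_below_permutation_null(self):
        """PLV of independent band-passed noise stays under the permutation 95th pct."""
        rng = np.random.default_rng(7)
        x = rng.standard_normal(1000)
        y = rng.standard_normal(1000)
        observed = sf.plv(x, y, band="high_gamma")
        # permutation oracle: circularly shift one signal
        null = [
            sf.plv(x, np.roll(y, int(s)), band="high_gamma")
            for s in rng.integers(50, 950, size=200)
        ]
        assert observed < np.percentile(null, 95)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sf.plv(np.zeros(1000), np.ones(1000) * 2.0, band="high_gamma")

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 100.0))
    def test_symmetry_bounds_and_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(600)
        y = rng.standard_normal(600)
        v1 = sf.plv(x, y, band="high_gamma")
        v2 = sf.plv(y, x, band="high_gamma")
        assert 0.0 <= v1 <= 1.0
        assert v1 == pytest.approx(v2, abs=1e-12)
        # per-channel amplitude scaling leaves PLV unchanged
        assert sf.plv(x * scale, y, band="high_gamma") == pytest.approx(v1, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 50.0))
    def test_band_power_scales_linearly(self, seed, scale):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(600)
        base = sf.band_power(x, "beta", FS)
        assert sf.band_power(x * scale, "beta", FS) == pytest.approx(base * scale, rel=1e-9)


class TestFeatureMatrix:
    def test_plv_feature_count_for_96_sites(self, long_tone_recording):
        windows = sf.extract_windows(long_tone_recording, None, length_ms=1000)[:2]
        fm = sf.build_feature_matrix(long_tone_recording, windows, "high_gamma", "plv")
        assert fm.n_features == 96 * 95 // 2 == 4560
        assert np.all((fm.values >= 0) & (fm.values <= 1))

    def test_single_window_single_row(self, long_tone_recording):
        windows = sf.extract_windows(long_tone_recording, None, length_ms=1000)[:1]
        fm = sf.build_feature_matrix(long_tone_recording, windows, "beta", "band_power")
        assert fm.values.shape == (1, 96)
        assert np.all(fm.values >= 0)

    def test_plv_columns_match_pairwise_recomputation(self, long_tone_recording):
        """Spot-check 10 random pairs against the standalone PLV implementation."""
        rec = long_tone_recording
        windows = sf.extract_windows(rec, None, length_ms=1000)[:1]
        fm = sf.build_feature_matrix(rec, windows, "high_gamma", "plv", pad_ms=0.0)
        w = windows[0]
        i0 = int(w.start_s * rec.fs_hz)
        seg = rec.data[:, i0:i0 + 1000].astype(float)
        rng = np.random.default_rng(8)
        for col in rng.choice(fm.n_features, size=10, replace=False):
            j, k = fm.descriptors[col]
            expected = sf.plv(seg[j], seg[k], band="high_gamma")
            assert fm.values[0, col] == pytest.approx(expected, abs=1e-9)

    def test_labels_by_condition_and_frequency(self, long_tone_recording):
        windows = sf.extract_windows(long_tone_recording, None, length_ms=1000,
                                     samples_per_label=3, seed=1)
        fm_c = sf.build_feature_matrix(long_tone_recording, windows, "beta", "band_power")
        assert set(fm_c.labels) == {"sound", "spontaneous"}
        fm_f = sf.build_feature_matrix(
            long_tone_recording, windows, "beta", "band_power", label_by="frequency"
        )
        assert set(fm_f.labels) == {"12000", "22000", "32000", "50000"}


class TestAepAmplitude:
    def test_flat_trace(self):
        p1, spont = sf.aep_amplitude(np.zeros((3, 1000)), 0.5, FS)
        assert np.all(p1 == 0) and np.all(spont == 0)

    def test_constructed_trace_arithmetic(self):
        """Post-onset minimum -120 uV and pre-onset minimum -15 uV -> (120, 15)."""
        x = np.zeros(1000)
        onset = 500
        x[onset + 22] = -120.0
        x[onset - 30] = -15.0
        p1, spont = sf.aep_amplitude(x[None, :], onset / FS, FS)
        assert p1[0] == pytest.approx(120.0)
        assert spont[0] == pytest.approx(15.0)

    def test_insufficient_context_rejected(self):
        with pytest.raises(ValueError):
            sf.aep_amplitude(np.zeros((1, 100)), 0.02, FS)

    def test_planted_aep_exceeds_spontaneous_at_matched_sites(self, site_map):
        """P1 > spontaneous amplitude in >= 95% of trials at CF-matched sites."""
        sched = cc.generate_tone_burst_protocol(
            [20000.0], [80.0], repeats=100, iti_ms=600, seed=12
        )
        rec = cc.simulate_lfp_session(site_map, sched, seed=12)
        cf = site_map.cf_hz
        matched = np.flatnonzero(
            np.isfinite(cf) & (np.abs(np.log2(cf / 20000.0)) < 0.2)
        )
        assert len(matched) >= 2
        wins = np.zeros(len(matched))
        total = 0
        for onset in rec.schedule.events["onset_s"]:
            p1, spont = sf.aep_amplitude(rec.data, onset, rec.fs_hz)
            wins += p1[matched] > spont[matched]
            total += 1
        assert np.all(wins / total >= 0.95)

    def test_aep_feature_matrix_layout(self, site_map):
        sched = cc.generate_tone_burst_protocol([13000.0], [60.0], repeats=5, seed=13)
        rec = cc.simulate_lfp_session(site_map, sched, seed=13)
        fm = sf.build_aep_feature_matrix(rec, frequency_hz=13000.0)
        assert fm.values.shape == (10, 96)  # 5 sound + 5 spontaneous rows
        assert (fm.labels == "sound").sum() == 5
        assert np.all(fm.values >= 0)
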