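"""Denoising, trimming, R-peak detection and segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morsebeat.preprocess import (denoise, detect_r_peaks, moving_average,
                                  remove_baseline, segment_beats,
                                  smooth_highfreq, trim_edges)
from morsebeat.records import EcgRecord
from morsebeat.synthetic import (NoiseSpec, QUIET, sample_subject_template,
                                 synthesize_recording, white_std_for_snr)

from conftest import match_peaks


def _rec(x, fs=1000.0):
    return EcgRecord(samples=np.asarray(x, dtype=float), fs=fs)


class TestMovingAverage:
    def test_constant_signal_is_fixed_point(self):
        x = np.full(100, 3.7)
        assert np.allclose(moving_average(x, 11), 3.7)
        assert np.allclose(moving_average(x, 10), 3.7)

    def test_impulse_spreads_to_window_of_one_over_width(self):
        x = np.zeros(100)
        x[50] = 1.0
        out = moving_average(x, 10)
        assert np.isclose(out.sum(), 1.0)
        assert np.count_nonzero(out) == 10
        assert np.allclose(out[out > 0], 0.1)

    def test_linear_ramp_interior_equals_window_mean(self):
        x = np.arange(50.0)
        out = moving_average(x, 5)
        # direct-summation oracle at interior samples
        for i in range(10, 40):
            assert out[i] == pytest.approx(np.mean(x[i - 2:i + 3]))
            assert out[i] == pytest.approx(float(i))

    @pytest.mark.parametrize("width", [0, -3, 101])
    def test_invalid_width_rejected(self, width):
        with pytest.raises(ValueError):
            moving_average(np.zeros(100), width)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(1, 30), st.floats(-3, 3), st.floats(-3, 3),
           st.integers(0, 2 ** 31 - 1))
    def test_linearity(self, width, alpha, beta, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 40))
        lhs = moving_average(alpha * x + beta * y, width)
        rhs = alpha * moving_average(x, width) + beta * moving_average(y, width)
        assert np.allclose(lhs, rhs, atol=1e-10)


class TestBaselineAndSmoothing:
    def test_constant_record_maps_to_zero(self):
        out = remove_baseline(_rec(np.full(2000, 1.23)))
        assert np.allclose(out.samples, 0.0)

    def test_slow_drift_attenuated_by_at_least_90_percent(self):
        # evaluate the moving-average response at 0.3 Hz and subtract:
        # residual amplitude must drop well below 10% of the input
        fs, width = 1000.0, 500
        t = np.arange(8000) / fs
        drift = np.sin(2 * np.pi * 0.3 * t)
        out = remove_baseline(_rec(drift, fs), width).samples
        interior = out[1000:-1000]
        assert np.max(np.abs(interior)) < 0.1

    def test_baseline_removal_improves_beat_train_correlation(self):
        tpl = sample_subject_template(3)
        rec, _ = synthesize_recording(tpl, 20.0, noise=QUIET, seed=3)
        clean = rec.samples
        t = np.arange(clean.size) / rec.fs
        drifted = clean + 0.5 * np.sin(2 * np.pi * 0.3 * t)
        out = remove_baseline(_rec(drifted)).samples
        def corr(a, b):
            return np.corrcoef(a, b)[0, 1]
        assert corr(out, clean) > corr(drifted, clean)

    def test_100hz_tone_nulled_by_width_10_average(self):
        # 100 Hz is an exact zero of the 10-sample uniform filter at 1 kHz
        fs = 1000.0
        t = np.arange(4000) / fs
        tone = np.sin(2 * np.pi * 100.0 * t)
        out = smooth_highfreq(_rec(tone, fs), 10).samples
        assert np.max(np.abs(out[100:-100])) < 0.01

    def test_smoothing_reduces_white_noise_variance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(5000)
        out = smooth_highfreq(_rec(x), 10).samples
        assert out.var() < x.var()

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError):
            remove_baseline(_rec(np.zeros(300)), 500)
        with pytest.raises(ValueError):
            smooth_highfreq(_rec(np.zeros(5)), 10)


class TestTrimEdges:
    def test_length_arithmetic(self):
        out = trim_edges(_rec(np.arange(2000.0)), 600)
        assert len(out) == 800
        assert out.samples[0] == 600.0

    def test_zero_trim_is_identity(self):
        x = np.arange(100.0)
        out = trim_edges(_rec(x), 0)
        assert np.array_equal(out.samples, x)

    def test_single_middle_sample_survives(self):
        x = np.arange(1201.0)
        out = trim_edges(_rec(x), 600)
        assert len(out) == 1 and out.samples[0] == 600.0

    def test_composition_equals_combined_trim(self):
        x = np.arange(3000.0)
        once = trim_edges(trim_edges(_rec(x), 400), 200)
        combined = trim_edges(_rec(x), 600)
        assert np.array_equal(once.samples, combined.samples)

    def test_overlong_trim_rejected(self):
        with pytest.raises(ValueError):
            trim_edges(_rec(np.zeros(1200)), 600)


class TestDetectRPeaks:
    def test_all_zero_record_yields_no_peaks(self):
        assert detect_r_peaks(_rec(np.zeros(5000))).size == 0

    def test_nonfinite_samples_rejected(self):
        x = np.zeros(5000)
        rec = _rec(x)
        rec.samples[10] = np.nan
        with pytest.raises(ValueError):
            detect_r_peaks(rec)

    def test_clean_recording_recovered_exactly(self):
        tol_s = 0.02
        for seed in range(3):
            tpl = sample_subject_template(seed + 50)
            rec, truth = synthesize_recording(tpl, 30.0, noise=QUIET,
                                              seed=seed)
            clean = denoise(rec)
            peaks = detect_r_peaks(clean)
            truth_in = truth[(truth >= 600) & (truth < len(rec) - 600)] - 600
            tp, fp, fn = match_peaks(peaks, truth_in, tol_s * rec.fs)
            assert fn == 0 and fp == 0

    def test_inverted_polarity_still_detected(self):
        tpl = sample_subject_template(11)
        rec, truth = synthesize_recording(tpl, 20.0, noise=QUIET, seed=11)
        flipped = rec.replace_samples(-rec.samples)
        peaks = detect_r_peaks(denoise(flipped))
        truth_in = truth[(truth >= 600) & (truth < len(rec) - 600)] - 600
        tp, fp, fn = match_peaks(peaks, truth_in, 0.02 * rec.fs)
        assert fn == 0 and fp == 0

    def test_peaks_respect_refractory_spacing(self):
        tpl = sample_subject_template(4)
        rec, _ = synthesize_recording(
            tpl, 30.0, noise=NoiseSpec(white_std=0.1), seed=4)
        peaks = detect_r_peaks(denoise(rec))
        assert np.all(np.diff(peaks) >= int(0.25 * rec.fs))

    def test_noisy_recording_sensitivity_and_precision(self):
        # 10 dB white-noise SNR, ~60 beats, +-20 ms tolerance
        tpl = sample_subject_template(21)
        sigma = white_std_for_snr(tpl, 10.0)
        dur = 62 * tpl.rr_mean
        rec, truth = synthesize_recording(
            tpl, dur, noise=NoiseSpec(white_std=sigma), seed=21)
        peaks = detect_r_peaks(denoise(rec))
        truth_in = truth[(truth >= 600) & (truth < len(rec) - 600)] - 600
        tp, fp, fn = match_peaks(peaks, truth_in, 0.02 * rec.fs)
        assert tp / (tp + fn) >= 0.99
        assert tp / (tp + fp) >= 0.99


class TestSegmentBeats:
    def test_window_exactly_fitting_record(self):
        rec = _rec(np.arange(784.0))
        segs = segment_beats(rec, [392], beat_length=784)
        assert len(segs) == 1
        assert np.array_equal(segs[0].samples, rec.samples)

    def test_boundary_crossing_window_dropped(self):
        rec = _rec(np.arange(784.0))
        assert segment_beats(rec, [10], beat_length=784) == []

    def test_all_interior_windows_kept_with_exact_length(self):
        fs = 1000.0
        period = 900
        peaks = 500 + period * np.arange(60)
        n = int(peaks[-1] + 500)
        rec = _rec(np.zeros(n), fs)
        segs = segment_beats(rec, peaks, beat_length=784)
        assert len(segs) == 60
        assert all(len(s) == 784 for s in segs)

    def test_out_of_bounds_peak_rejected(self):
        with pytest.raises(ValueError):
            segment_beats(_rec(np.zeros(1000)), [1000])
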