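"""Morse wavelet construction, scale grids, CWT and scalograms."""

import numpy as np
import pytest

from morsebeat.morse import (MorseParams, beta_from_tbp, beat_scalogram,
                             build_scale_grid, cwt, morse_psi_hat,
                             morse_time_std, peak_frequency, scalogram)

from conftest import time_domain_cwt


class TestMorseParameterization:
    def test_beta_from_time_bandwidth_product(self):
        assert beta_from_tbp(60.0, 3.0) == pytest.approx(20.0)
        assert beta_from_tbp(1.0, 1.0) == pytest.approx(1.0)
        # Bessel-wavelet setting: beta=8, gamma=0.25 -> P^2 = 2
        assert beta_from_tbp(2.0, 0.25) == pytest.approx(8.0)

    @pytest.mark.parametrize("tbp,gamma", [(0, 3), (-1, 3), (60, 0)])
    def test_nonpositive_inputs_rejected(self, tbp, gamma):
        with pytest.raises(ValueError):
            beta_from_tbp(tbp, gamma)

    def test_default_params_match_standard_setting(self, params):
        assert params.gamma == 3.0 and params.tbp == 60.0
        assert params.beta == pytest.approx(20.0)
        assert params.voices_per_octave == 12
        assert params.norm_constant > 0


class TestMorseFilter:
    def test_zero_and_negative_frequencies_give_zero(self, params):
        assert morse_psi_hat(0.0, params) == 0.0
        assert morse_psi_hat(-1.0, params) == 0.0
        w = np.linspace(-5, 0, 100)
        assert np.all(morse_psi_hat(w, params) == 0.0)

    def test_matches_direct_formula_on_dense_grid(self, params):
        w = np.linspace(1e-3, 6.0, 10_000)
        a, b, g = params.norm_constant, params.beta, params.gamma
        direct = a * w ** b * np.exp(-w ** g)
        assert np.allclose(morse_psi_hat(w, params), direct,
                           rtol=1e-12, atol=0)

    def test_unimodal_on_positive_axis(self, params):
        w = np.linspace(1e-3, 6.0, 5000)
        vals = morse_psi_hat(w, params)
        d = np.diff(vals)
        turn = np.argmax(d < 0)
        assert np.all(d[:turn] > 0) and np.all(d[turn:] < 0)

    def test_peak_value_is_two_under_peak_normalization(self, params):
        assert morse_psi_hat(peak_frequency(params), params) == \
            pytest.approx(2.0, rel=1e-12)

    def test_peak_frequency_matches_grid_argmax(self, params):
        w = np.linspace(1e-4, 6.0, 200_001)
        w_star = w[np.argmax(morse_psi_hat(w, params))]
        assert peak_frequency(params) == pytest.approx(w_star, rel=1e-4)
        assert peak_frequency(params) == pytest.approx(1.88207, rel=1e-4)

    def test_peak_frequency_special_cases(self):
        assert peak_frequency(MorseParams(gamma=2.0, tbp=4.0)) == \
            pytest.approx(1.0)  # beta == gamma
        assert peak_frequency(MorseParams(gamma=1.0, tbp=1.0)) == \
            pytest.approx(1.0)  # Cauchy case

    def test_peak_frequency_matches_argmax_for_random_params(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            gamma = rng.uniform(0.25, 5.0)
            beta = rng.uniform(1.0, 40.0)
            p = MorseParams(gamma=gamma, tbp=beta * gamma)
            wp = peak_frequency(p)
            w = np.linspace(wp / 20, wp * 6, 200_001)
            w_star = w[np.argmax(morse_psi_hat(w, p))]
            assert wp == pytest.approx(w_star, rel=1e-3)


class TestScaleGrid:
    def test_adjacent_ratio_is_one_voice(self, params):
        grid = build_scale_grid(784, 1000.0, params)
        ratios = grid.scales[1:] / grid.scales[:-1]
        assert np.allclose(ratios, 2.0 ** (1.0 / 12.0), rtol=1e-12)

    def test_center_frequency_halves_when_scale_doubles(self, params):
        grid = build_scale_grid(784, 128.0, params)
        v = params.voices_per_octave
        assert np.allclose(grid.center_frequencies[:-v] /
                           grid.center_frequencies[v:], 2.0, rtol=1e-12)
        assert np.all(np.diff(grid.center_frequencies) < 0)

    def test_scale_count_follows_endpoint_rule(self, params):
        grid = build_scale_grid(784, 128.0, params)
        # endpoints: smallest scale has negligible response at Nyquist,
        # largest keeps the time support within a quarter of the signal
        assert morse_psi_hat(grid.scales[0] * np.pi, params) == \
            pytest.approx(2e-8, rel=1e-6)
        assert grid.scales[-1] * morse_time_std(params) <= 784 / 4.0
        n_oct = np.log2(grid.scales[-1] / grid.scales[0])
        assert len(grid) == int(np.floor(12 * n_oct)) + 1

    def test_degenerate_signal_length_rejected(self, params):
        with pytest.raises(ValueError):
            build_scale_grid(2, 1000.0, params)


class TestCwt:
    def test_zero_signal_gives_zero_matrix(self, params):
        grid = build_scale_grid(128, 1000.0, params)
        assert np.all(cwt(np.zeros(128), grid, params) == 0)

    def test_linearity(self, params):
        rng = np.random.default_rng(5)
        grid = build_scale_grid(96, 1000.0, params)
        x, y = rng.standard_normal((2, 96))
        lhs = cwt(2.5 * x - 1.5 * y, grid, params)
        rhs = 2.5 * cwt(x, grid, params) - 1.5 * cwt(y, grid, params)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_sinusoid_ridge_within_one_voice(self, params):
        fs, n, f0 = 1000.0, 784, 40.0
        grid = build_scale_grid(n, fs, params)
        t = np.arange(n) / fs
        coeffs = cwt(np.sin(2 * np.pi * f0 * t), grid, params)
        energy = np.abs(coeffs[:, 100:-100]).mean(axis=1)
        fc = grid.center_frequencies[np.argmax(energy)]
        voice = 2.0 ** (1.0 / 12.0)
        assert f0 / voice <= fc <= f0 * voice

    def test_matches_time_domain_oracle(self, params):
        rng = np.random.default_rng(0)
        n = 64
        grid = build_scale_grid(n, 128.0, params)
        x = rng.standard_normal(n)
        fft_route = cwt(x, grid, params)
        idx = np.linspace(0, len(grid) - 1, 8).astype(int)
        oracle = time_domain_cwt(x, grid.scales[idx], params)
        for k, j in enumerate(idx):
            scale_max = np.max(np.abs(fft_route[j]))
            err = np.max(np.abs(oracle[k] - fft_route[j])) / scale_max
            assert err <= 1e-6

    def test_circular_shift_covariance_in_periodic_mode(self, params):
        rng = np.random.default_rng(1)
        n, shift = 128, 17
        grid = build_scale_grid(n, 1000.0, params)
        x = rng.standard_normal(n)
        base = cwt(x, grid, params, boundary="periodic")
        shifted = cwt(np.roll(x, shift), grid, params, boundary="periodic")
        assert np.allclose(shifted, np.roll(base, shift, axis=1),
                           atol=1e-10)

    def test_length_mismatch_rejected(self, params):
        grid = build_scale_grid(128, 1000.0, params)
        with pytest.raises(ValueError):
            cwt(np.zeros(100), grid, params)


class TestScalogram:
    def test_modulus_examples(self, params):
        grid = build_scale_grid(64, 1000.0, params)
        mat = np.zeros((len(grid), 64), dtype=complex)
        mat[0, 0] = -3.0
        mat[1, 1] = 3.0 + 4.0j
        s = scalogram(mat, grid)
        assert s.magnitude[0, 0] == 3.0
        assert s.magnitude[1, 1] == pytest.approx(5.0)
        assert s.magnitude.sum() == pytest.approx(8.0)

    def test_entries_nonnegative_and_scale_with_gain(self, params):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(96)
        s1 = beat_scalogram(x, 1000.0, params)
        s2 = beat_scalogram(-2.0 * x, 1000.0, params)
        assert np.all(s1.magnitude >= 0)
        assert np.allclose(s2.magnitude, 2.0 * s1.magnitude, atol=1e-12)

    def test_chirp_ridge_monotone_in_time(self, params):
        fs, n = 1000.0, 784
        t = np.arange(n) / fs
        f0, f1 = 20.0, 120.0
        chirp = np.sin(2 * np.pi * (f0 + (f1 - f0) / 2 * t / t[-1]) * t)
        s = beat_scalogram(chirp, fs, params)
        cols = np.arange(100, n - 100)
        ridge = s.scale_axis.center_frequencies[
            np.argmax(s.magnitude[:, cols], axis=0)]
        # median-filter the per-column ridge, then demand a monotone trend
        k = 21
        sm = np.array([np.median(ridge[i:i + k])
                       for i in range(ridge.size - k)])
        assert np.all(np.diff(sm) >= 0)
        assert sm[-1] > sm[0] * 2
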