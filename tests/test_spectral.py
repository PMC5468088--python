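"""Multitaper PSDs and the normalized beta cursor."""

import numpy as np
import pytest

from betapop.spectral import (
    PSD,
    beta_cursor_value,
    band_power,
    cursor_trace,
    detrended_spectrogram,
    multitaper_psd,
    normalized_beta_trace,
    zscored_psd,
)

FS = 1000.0


def test_zero_segment_gives_zero_psd():
    psd = multitaper_psd(np.zeros(200), FS)
    assert np.all(psd.power == 0)


def test_sine_band_power_matches_time_domain_variance():
    # Parseval: total integrated power equals signal variance.  On a 200 ms
    # window the 5-taper bandwidth is +/-15 Hz, so the tone's power lives in
    # 30 +/- 15 Hz; on a 1 s window (1 Hz grid) it concentrates in 25-40 Hz.
    t200 = np.arange(200) / FS
    x200 = np.sin(2 * np.pi * 30 * t200)
    psd = multitaper_psd(x200, FS)
    df = psd.frequencies[1] - psd.frequencies[0]
    total = float(np.sum(psd.power)) * df
    assert total == pytest.approx(np.mean(x200**2), rel=0.10)

    t1s = np.arange(1000) / FS
    x1s = np.sin(2 * np.pi * 30 * t1s)
    psd1 = multitaper_psd(x1s, FS)
    df1 = psd1.frequencies[1] - psd1.frequencies[0]
    assert band_power(psd1, (25, 40)) * df1 == pytest.approx(0.5, rel=0.10)


def test_white_noise_power_flat_across_bands(rng):
    # Monte-Carlo oracle: average many realizations, compare two band means
    n_reps, n = 1000, 200
    acc = np.zeros(n // 2 + 1)
    for _ in range(n_reps):
        acc += multitaper_psd(rng.standard_normal(n), FS).power
    acc /= n_reps
    freqs = np.fft.rfftfreq(n, 1 / FS)
    low = acc[(freqs >= 50) & (freqs <= 200)].mean()
    high = acc[(freqs >= 250) & (freqs <= 400)].mean()
    assert low == pytest.approx(high, rel=0.05)


def test_all_nan_segment_raises():
    with pytest.raises(ValueError, match="NaN"):
        multitaper_psd(np.full(100, np.nan), FS)


class TestBetaCursorValue:
    def test_flat_spectrum_1hz_grid(self):
        # inclusive bins: 16 beta bins / 100 broadband bins
        psd = PSD(frequencies=np.arange(0.0, 501.0), power=np.ones(501))
        assert beta_cursor_value([psd] * 3) == pytest.approx(0.16, abs=1e-12)

    def test_all_power_in_beta_band(self):
        power = np.zeros(501)
        power[30] = 5.0
        psd = PSD(frequencies=np.arange(0.0, 501.0), power=power)
        assert beta_cursor_value(psd) == 1.0

    def test_power_outside_beta_band(self):
        power = np.zeros(501)
        power[50:61] = 1.0
        psd = PSD(frequencies=np.arange(0.0, 501.0), power=power)
        assert beta_cursor_value(psd) == 0.0

    def test_zero_broadband_raises(self):
        psd = PSD(frequencies=np.arange(0.0, 501.0), power=np.zeros(501))
        with pytest.raises(ValueError, match="broadband"):
            beta_cursor_value(psd)

    def test_invariant_under_global_rescaling(self, rng):
        x = rng.standard_normal(200)
        p1 = multitaper_psd(x, FS)
        p2 = multitaper_psd(10.0 * x, FS)
        assert beta_cursor_value(p1) == pytest.approx(beta_cursor_value(p2), rel=1e-9)


class TestCursorTrace:
    def test_update_count(self, rng):
        trace = cursor_trace(rng.standard_normal((2000, 3)), FS)
        assert trace.times.size == 19  # 2.0 s, 0.2 s trailing windows, 0.1 s cadence
        np.testing.assert_allclose(trace.times[0], 0.2)
        np.testing.assert_allclose(trace.times[-1], 2.0)

    def test_constant_beta_maps_through_transform(self, rng):
        # pure in-band tone: beta_est ~ constant; y = 10*beta + 1
        t = np.arange(2000) / FS
        x = np.column_stack([np.sin(2 * np.pi * 30 * t)] * 3)
        trace = cursor_trace(x, FS, transform=(10.0, 1.0))
        expected = 10.0 * trace.beta_est + 1.0
        # boxcar of a nearly constant series stays near it
        np.testing.assert_allclose(trace.screen_y[1:], expected[1:], atol=0.05)

    def test_boxcar_halves_a_step(self):
        from betapop.spectral import _boxcar2

        x = np.array([0.0, 0.0, 1.0, 1.0])
        np.testing.assert_allclose(_boxcar2(x), [0.0, 0.0, 0.5, 1.0])

    def test_two_band_variant_adds_x_axis(self, rng):
        trace = cursor_trace(
            rng.standard_normal((1000, 3)), FS, x_band=(1.0, 10.0)
        )
        assert trace.screen_x is not None
        assert trace.screen_x.size == trace.screen_y.size


class TestNormalizedBetaTrace:
    def test_matches_cursor_trace_at_shared_timestamps(self, rng):
        x = rng.standard_normal((1500, 3))
        trace = cursor_trace(x, FS)
        times, beta = normalized_beta_trace(x, FS, step_s=0.01)
        shared = np.isin(np.round(times, 6), np.round(trace.times, 6))
        np.testing.assert_allclose(beta[shared], trace.beta_est, rtol=1e-10)

    def test_pure_beta_tone_dominates(self):
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * 30 * t)
        # 200 ms windows: taper bandwidth +/-15 Hz leaks part of the tone
        # below 25 Hz, but beta still dominates broadband
        _, beta = normalized_beta_trace(x, FS)
        assert np.all(beta > 0.6)
        # 1 s windows (1 Hz grid): the tone concentrates inside 25-40 Hz
        _, beta1 = normalized_beta_trace(x, FS, window_s=1.0)
        assert np.all(beta1 > 0.98)

    def test_white_noise_expectation(self, rng):
        # flat spectrum on the 5 Hz grid of 200 ms windows: 4/20 bins = 0.2
        _, beta = normalized_beta_trace(rng.standard_normal(200_000), FS)
        assert beta.mean() == pytest.approx(0.2, abs=0.02)


class TestDetrendedSpectrogram:
    def test_linear_in_frequency_input_flattens_to_zero(self, rng):
        # white noise has flat (slope 0) expected spectrum; the fitted
        # intercept absorbs it, residual averages to ~0
        trials = rng.standard_normal((20, 1000))
        _, _, mat, coef = detrended_spectrogram(trials, FS)
        assert abs(mat.mean()) < 1e-12  # residuals of the fit are centered

    def test_transient_tone_leaves_localized_positive_residual(self, rng):
        # a 30 Hz tone burst in [0.3, 0.5] s should survive detrending as a
        # positive residual confined to the beta band around that time
        t = np.arange(1000) / FS
        burst = np.where((t >= 0.3) & (t < 0.5), np.sin(2 * np.pi * 30 * t), 0.0)
        trials = 0.5 * rng.standard_normal((20, 1000)) + burst
        times, freqs, mat, _ = detrended_spectrogram(trials, FS)
        f30 = np.argmin(np.abs(freqs - 30))
        in_burst = (times >= 0.3) & (times <= 0.5)
        assert mat[f30, in_burst].mean() > 5 * np.abs(mat[f30, ~in_burst]).mean()

    def test_single_frequency_bin_raises(self):
        with pytest.raises(ValueError, match="single frequency"):
            detrended_spectrogram(np.ones((2, 100)), FS, window_s=0.001)


class TestZscoredPsd:
    def test_zscore_columns_centered_and_scaled(self, rng):
        X = rng.standard_normal((40, 16)) * 3 + 5
        labels = np.repeat([1, 2], 20)
        freqs, means = zscored_psd(X, np.arange(16), labels)
        # group means weighted by size must cancel (overall z mean is 0)
        pooled = 0.5 * (means[1] + means[2])
        np.testing.assert_allclose(pooled, 0.0, atol=1e-12)

    def test_constructed_group_offset_is_symmetric(self):
        # two equal groups differing by +delta at one frequency
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 8))
        X[50:, 3] += 2.0
        labels = np.repeat([0, 1], 50)
        freqs, means = zscored_psd(X, np.arange(8), labels)
        assert means[1][3] > 0 > means[0][3]
        np.testing.assert_allclose(means[1][3], -means[0][3], atol=1e-12)

    def test_single_target_means_are_zero(self, rng):
        X = rng.standard_normal((30, 10))
        _, means = zscored_psd(X, np.arange(10), np.zeros(30))
        np.testing.assert_allclose(means[0.0], 0.0, atol=1e-12)

    def test_zero_variance_frequency_dropped_with_warning(self, rng):
        X = rng.standard_normal((20, 5))
        X[:, 2] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            freqs, _ = zscored_psd(X, np.arange(5), np.zeros(20))
        assert 2 not in freqs
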