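"""Spectral estimation, Simpson band integration and differential entropy."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from stratnorm.features import (
    BANDS,
    BandDefinition,
    PSDEstimate,
    band_power,
    bandpass,
    differential_entropy,
    extract_features,
    gaussian_entropy,
    multitaper_psd,
    welch_psd,
)

from conftest import make_tiny_dataset

FS = 200.0
THETA, ALPHA, BETA, GAMMA = BANDS


def _total_power(psd):
    return integrate.trapezoid(psd.density, psd.freqs, axis=-1)


@pytest.mark.parametrize("method", [welch_psd, multitaper_psd])
class TestPSDCommon:
    def test_zero_signal_zero_density(self, method):
        psd = method(np.zeros((2, 2000)), FS)
        np.testing.assert_allclose(psd.density, 0.0, atol=1e-20)
        assert (psd.density >= 0).all()

    def test_parseval_white_noise(self, method):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((1, int(120 * FS)))
        psd = method(x, FS)
        total = _total_power(psd)[0]
        assert total == pytest.approx(np.var(x), rel=0.05)

    def test_uniform_grid(self, method):
        psd = method(np.ones((1, 4000)) * 0.0, FS)
        steps = np.diff(psd.freqs)
        np.testing.assert_allclose(steps, steps[0])
        assert psd.freqs[0] >= 0


class TestWelch:
    def test_sinusoid_power_in_alpha(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)[np.newaxis, :]
        psd = welch_psd(x, FS)
        total = _total_power(psd)[0]
        assert total == pytest.approx(0.5, rel=0.05)
        in_alpha = band_power(psd, ALPHA)[0]
        assert in_alpha >= 0.95 * total

    def test_too_short_trial_rejected(self):
        with pytest.raises(ValueError, match="shorter than one"):
            welch_psd(np.zeros((1, 50)), FS, win_s=0.5)

    def test_theta_band_has_enough_grid_points(self):
        # 0.5 s windows alone would give a 2 Hz grid; zero padding must
        # refine it so the 3 Hz wide theta band is integrable.
        psd = welch_psd(np.random.default_rng(0).standard_normal((1, 400)), FS)
        assert ((psd.freqs >= 4) & (psd.freqs <= 7)).sum() >= 3


class TestMultitaper:
    def test_cross_method_band_powers_on_ar1(self):
        rng = np.random.default_rng(3)
        n = int(240 * FS)
        eps = rng.standard_normal(n + 500)
        x = np.empty(n + 500)
        x[0] = eps[0]
        for i in range(1, len(x)):  # AR(1), phi=0.5: smooth wideband spectrum
            x[i] = 0.5 * x[i - 1] + eps[i]
        x = x[500:][np.newaxis, :]
        w, m = welch_psd(x, FS), multitaper_psd(x, FS)
        for band in BANDS:
            assert band_power(m, band)[0] == pytest.approx(
                band_power(w, band)[0], rel=0.10
            )

    def test_matches_mne_reference(self):
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(5)
        x = rng.standard_normal((2, int(30 * FS)))
        ours = multitaper_psd(x, FS, nw=4)
        ref_psd, ref_freqs = mne.time_frequency.psd_array_multitaper(
            x, FS, adaptive=False, low_bias=False, bandwidth=2 * 4.0 / 30.0,
            normalization="full", verbose="error",
        )
        ref = PSDEstimate(freqs=ref_freqs, density=ref_psd)
        for band in BANDS:
            np.testing.assert_allclose(
                band_power(ours, band), band_power(ref, band), rtol=0.05
            )


class TestBandPower:
    def _psd(self, f_lo, f_hi, fn, step=0.25):
        freqs = np.arange(0, 60 + step, step)
        return PSDEstimate(freqs=freqs, density=fn(freqs)[np.newaxis, :])

    def test_constant_density_is_bandwidth(self):
        psd = self._psd(4, 7, lambda f: np.ones_like(f))
        assert band_power(psd, THETA)[0] == pytest.approx(3.0, abs=1e-12)

    def test_exact_for_linear_density(self):
        psd = self._psd(8, 13, lambda f: f)
        assert band_power(psd, ALPHA)[0] == pytest.approx(52.5, abs=1e-9)

    def test_exact_for_quadratic_density(self):
        psd = self._psd(14, 30, lambda f: f**2)
        assert band_power(psd, BETA)[0] == pytest.approx(
            (30**3 - 14**3) / 3, rel=1e-12
        )

    def test_matches_fine_trapezoid_for_smooth_density(self):
        step = 0.01
        freqs = np.arange(0, 60, step)
        density = np.exp(-((freqs - 20) ** 2) / 50)
        psd = PSDEstimate(freqs=freqs, density=density[np.newaxis, :])
        for band in BANDS:
            mask = (freqs >= band.f_lo) & (freqs <= band.f_hi)
            oracle = integrate.trapezoid(density[mask], freqs[mask])
            assert band_power(psd, band)[0] == pytest.approx(oracle, rel=0.005)

    def test_too_few_points_rejected(self):
        psd = PSDEstimate(
            freqs=np.arange(0, 101, 2.0),
            density=np.ones((1, 51)),
        )
        with pytest.raises(ValueError, match="grid points"):
            band_power(psd, THETA)

    def test_band_not_covered_rejected(self):
        psd = PSDEstimate(freqs=np.arange(0, 20, 0.5),
                          density=np.ones((1, 40)))
        with pytest.raises(ValueError, match="cover"):
            band_power(psd, GAMMA)


class TestBandpass:
    def test_passband_preserves_sinusoid(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass(x, FS, ALPHA)
        assert np.var(y) == pytest.approx(np.var(x), rel=0.05)

    def test_stopband_rejects_sinusoid(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass(x, FS, GAMMA)
        assert np.var(y) <= 0.01 * np.var(x)

    def test_zero_in_zero_out(self):
        np.testing.assert_allclose(bandpass(np.zeros(1000), FS, BETA), 0.0)


class TestDifferentialEntropy:
    def test_closed_form_anchors(self):
        assert gaussian_entropy(1.0 / (2 * math.pi * math.e)) == pytest.approx(
            0.0, abs=1e-12
        )
        assert gaussian_entropy(1.0) == pytest.approx(1.4189385332046727, abs=1e-12)

    def test_closed_form_matches_numeric_integration(self):
        # oracle: -\int f ln f for the fitted Gaussian density
        for var in (0.3, 1.0, 4.2):
            dist = stats.norm(scale=math.sqrt(var))
            lim = 12 * math.sqrt(var)
            oracle, _ = integrate.quad(
                lambda x: -dist.pdf(x) * dist.logpdf(x), -lim, lim
            )
            assert gaussian_entropy(var) == pytest.approx(oracle, abs=1e-6)

    def test_band_limited_noise_entropy_vs_nonparametric(self):
        # Band-passed Gaussian noise stays Gaussian; a nonparametric
        # entropy estimate on the samples must agree with the closed form.
        rng = np.random.default_rng(9)
        x = rng.standard_normal(int(120 * FS))
        res = differential_entropy(x, FS, BETA)
        est = stats.differential_entropy(bandpass(x, FS, BETA))
        assert res.entropy == pytest.approx(float(est), abs=0.05)
        assert not res.degenerate

    def test_zero_variance_flagged_degenerate(self):
        res = differential_entropy(np.zeros(2000), FS, ALPHA)
        assert res.entropy == -math.inf
        assert res.degenerate


class TestExtractFeatures:
    def test_62_channels_give_248_features(self):
        d = make_tiny_dataset(
            n_participants=1, n_trials=2, n_channels=62, fs=200.0,
            n_samples=400,
        )
        table = extract_features(d, "welch")
        assert table.n_features == 248

    def test_toy_column_names(self):
        d = make_tiny_dataset(
            n_participants=1, n_trials=2, n_channels=2, fs=200.0,
            n_samples=400,
        )
        table = extract_features(d, "welch")
        assert table.feature_names[:4] == [
            "c1_theta", "c1_alpha", "c1_beta", "c1_gamma",
        ]
        assert table.feature_names[-1] == "c2_gamma"
        assert table.n_features == 8

    def test_degenerate_de_channel_reported(self):
        d = make_tiny_dataset(n_participants=1, n_trials=2, n_channels=2,
                              fs=200.0, n_samples=400)
        for t in d.trials:
            t.signal[1] = 0.0
        with pytest.raises(ValueError, match="c2"):
            extract_features(d, "de")

    def test_unknown_method_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="method"):
            extract_features(tiny_dataset, "burg")

    @pytest.mark.parametrize("method", ["welch", "multitaper"])
    def test_power_scales_quadratically(self, method):
        d = make_tiny_dataset(n_participants=1, n_trials=2, n_channels=2,
                              fs=200.0, n_samples=2000, seed=4)
        for t in d.trials:
            t.signal = t.signal.astype(np.float64)
        base = extract_features(d, method)
        c = 3.7
        for t in d.trials:
            t.signal = t.signal * c
        scaled = extract_features(d, method)
        np.testing.assert_allclose(scaled.X, c**2 * base.X, rtol=1e-9)

    def test_de_shifts_by_log_of_scale(self):
        d = make_tiny_dataset(n_participants=1, n_trials=2, n_channels=2,
                              fs=200.0, n_samples=2000, seed=4)
        for t in d.trials:
            t.signal = t.signal.astype(np.float64)
        base = extract_features(d, "de")
        c = 3.7
        for t in d.trials:
            t.signal = t.signal * c
        scaled = extract_features(d, "de")
        np.testing.assert_allclose(scaled.X, base.X + math.log(c), rtol=0, atol=1e-9)


def test_welch_multitaper_feature_tables_correlate(mini_raw_features):
    """On long stationary synthetic trials the two PSD routes agree."""
    welch_t, multi_t = mini_raw_features
    for j in range(welch_t.n_features):
        r = np.corrcoef(welch_t.X[:, j], multi_t.X[:, j])[0, 1]
        assert r > 0.9
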