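"""Time-frequency transforms: STFT/CWT against direct-quadrature oracles,
inverse-transform reconstruction, admissibility, band filters, rendering."""

import numpy as np
import pytest

from eegemo.core import EEGRecording
from eegemo.timefreq import (
    AdmissibilityError,
    WaveletSpec,
    WindowSpec,
    admissibility_constant,
    bandpass_decompose,
    cwt,
    daughter_wavelet,
    default_scales,
    icwt,
    render_scalogram_image,
    segment_signal,
    stft,
)

from conftest import band_power


def brute_force_cwt(u, wavelet, scales):
    """Direct Riemann-sum quadrature of the defining CWT integral at every
    (scale, shift): the independent oracle for the fast FFT path."""
    t = np.arange(len(u))
    r = 0.5 if wavelet.normalization == "L2" else 1.0
    out = np.empty((len(scales), len(u)), dtype=complex)
    for j, m in enumerate(scales):
        for n in range(len(u)):
            out[j, n] = np.sum(u * np.conj(wavelet.time_domain((t - n) / m))) / m**r
    return out


class TestSTFT:
    def test_zero_signal_gives_zero_matrix(self):
        _, _, X = stft(np.zeros(64), WindowSpec("hann", 16), hop=8)
        assert np.all(X == 0)

    def test_linearity_in_signal(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        w = WindowSpec("hann", 32)
        _, _, X1 = stft(x, w, hop=8)
        _, _, X2 = stft(3.5 * x, w, hop=8)
        np.testing.assert_allclose(X2, 3.5 * X1, rtol=1e-12)

    def test_sinusoid_peak_matches_direct_quadrature(self):
        # 128-sample sinusoid, rectangular window: per-column magnitude
        # argmax lands at the bin nearest f0, and the whole matrix matches
        # a term-by-term evaluation of the windowed transform
        N, f0 = 128, 0.125
        x = np.sin(2 * np.pi * f0 * np.arange(N))
        w = WindowSpec("rectangular", 32)
        freqs, starts, X = stft(x, w, hop=16)
        k0 = np.argmin(np.abs(freqs - f0))
        assert np.all(np.argmax(np.abs(X), axis=0) == k0)
        warr = w.array()
        direct = np.empty_like(X)
        for c, s in enumerate(starts):
            for k in range(len(freqs)):
                t = np.arange(s, s + 32)
                direct[k, c] = np.sum(x[t] * warr * np.exp(-2j * np.pi * k * t / 32))
        np.testing.assert_allclose(X, direct, atol=1e-10)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            stft(np.array([]), WindowSpec("hann", 4), hop=1)
        with pytest.raises(ValueError):
            stft(np.ones(16), WindowSpec("hann", 4), hop=0)
        with pytest.raises(ValueError):
            stft(np.ones(8), WindowSpec("hann", 16), hop=4)


class TestCWT:
    def test_zero_signal_gives_zero_coefficients(self):
        w = WaveletSpec(family="morlet")
        S = cwt(np.zeros(64), w, default_scales(w, 1.0, n_scales=4, f_min=0.05, f_max=0.2))
        assert np.all(S.coefficients == 0)

    def test_daughter_identity_at_unit_scale_zero_shift(self):
        w = WaveletSpec(family="morlet", normalization="L1")
        t = np.linspace(-5, 5, 101)
        np.testing.assert_allclose(
            daughter_wavelet(w, 1.0, 0.0, t), w.time_domain(t), rtol=1e-12
        )

    @pytest.mark.parametrize("family", ["morlet", "morse"])
    def test_matches_brute_force_quadrature(self, family):
        # two-tone 64-sample signal, zero boundary: the FFT path must
        # agree with the direct double loop essentially to round-off
        N = 64
        t = np.arange(N)
        u = np.sin(2 * np.pi * 0.1 * t) + 0.5 * np.sin(2 * np.pi * 0.22 * t + 1.0)
        w = WaveletSpec(family=family)
        scales = default_scales(w, 1.0, n_scales=6, f_min=0.06, f_max=0.25)
        S = cwt(u, w, scales, boundary="zero")
        oracle = brute_force_cwt(u, w, scales)
        err = np.max(np.abs(S.coefficients - oracle)) / np.max(np.abs(oracle))
        assert err < 1e-6

    def test_shift_covariance_in_interior(self):
        rng = np.random.default_rng(2)
        N, shift = 256, 7
        base = rng.normal(size=N + shift)
        w = WaveletSpec(family="morlet")
        scales = default_scales(w, 1.0, n_scales=8, f_min=0.05, f_max=0.3)
        S1 = cwt(base[:N], w, scales, boundary="zero")
        S2 = cwt(base[shift : shift + N], w, scales, boundary="zero")
        # u2(t) = u1(t + shift) so W2(m, n) = W1(m, n + shift) away from edges
        margin = 100
        a = S1.coefficients[:, margin + shift : N - margin + shift]
        b = S2.coefficients[:, margin : N - margin]
        peak = np.max(np.abs(S1.coefficients))
        assert np.max(np.abs(a - b)) <= 1e-6 * peak

    def test_scalogram_shape_is_scales_by_samples(self):
        w = WaveletSpec()
        scales = default_scales(w, 200.0, n_scales=16)
        S = cwt(np.ones(300), w, scales)
        assert S.coefficients.shape == (16, 300)

    def test_rejects_bad_inputs(self):
        w = WaveletSpec()
        with pytest.raises(ValueError):
            cwt(np.ones(32), w, [])
        with pytest.raises(AdmissibilityError):
            cwt(np.ones(32), WaveletSpec(family="gaussian"), [2.0])


class TestICWT:
    def test_zero_coefficients_give_zero_signal(self):
        w = WaveletSpec(family="morlet")
        S = cwt(np.zeros(128), w, default_scales(w, 1.0, n_scales=8, f_min=0.05, f_max=0.3))
        assert np.allclose(icwt(S), 0.0)

    def test_linear_in_coefficients(self):
        rng = np.random.default_rng(3)
        u = rng.normal(size=200)
        w = WaveletSpec(family="morlet")
        S = cwt(u, w, default_scales(w, 1.0, n_scales=16, f_min=0.02, f_max=0.4))
        r1 = icwt(S)
        S.coefficients = 2.5 * S.coefficients
        np.testing.assert_allclose(icwt(S), 2.5 * r1, rtol=1e-10)

    @pytest.mark.parametrize("family", ["morlet", "morse"])
    def test_reconstructs_band_limited_signal(self, family):
        fs, N = 200.0, 1000
        t = np.arange(N) / fs
        u = (
            np.sin(2 * np.pi * 7 * t)
            + 0.7 * np.sin(2 * np.pi * 18 * t + 0.5)
            + 0.4 * np.sin(2 * np.pi * 24 * t + 1.2)
        )
        w = WaveletSpec(family=family)
        rec = icwt(cwt(u, w, default_scales(w, fs)))
        assert np.linalg.norm(rec - u) / np.linalg.norm(u) <= 0.05


class TestAdmissibility:
    def test_morlet_finite_positive_and_grid_stable(self):
        w = WaveletSpec(family="morlet")
        c = admissibility_constant(w)
        assert c > 0
        # refinement oracle: fine trapezoid on an explicit grid
        om = np.linspace(1e-6, 30, 400001)
        ref = np.trapezoid(np.abs(w.freq_domain(om)) ** 2 / om, om)
        assert abs(c - ref) < 1e-4

    def test_gaussian_bump_rejected(self):
        with pytest.raises(AdmissibilityError):
            admissibility_constant(WaveletSpec(family="gaussian"))

    def test_quadratic_in_amplitude(self):
        c1 = admissibility_constant(WaveletSpec(family="morse"))
        c2 = admissibility_constant(WaveletSpec(family="morse", amplitude=2.0))
        assert abs(c2 / c1 - 4.0) < 1e-9


class TestBandDecompose:
    def _recording(self, samples, fs=200.0):
        return EEGRecording(np.atleast_2d(samples), fs, 1, 0, 0)

    def test_alpha_sinusoid_lands_in_alpha(self):
        fs = 200.0
        t = np.arange(2000) / fs
        rec = self._recording(np.sin(2 * np.pi * 10 * t), fs)
        bands = bandpass_decompose(rec)
        total = band_power(rec.samples[0], fs, 0.5, 99)
        assert band_power(bands["alpha"][0], fs, 0.5, 99) / total >= 0.95
        assert band_power(bands["delta"][0], fs, 0.5, 99) / total <= 0.01

    def test_zero_signal_stays_zero(self):
        out = bandpass_decompose(self._recording(np.zeros(1000)))
        for sig in out.values():
            assert np.allclose(sig, 0.0)

    def test_white_noise_power_tracks_bandwidth(self):
        rng = np.random.default_rng(5)
        fs = 200.0
        rec = self._recording(rng.normal(size=200_000), fs)
        out = bandpass_decompose(rec)
        widths = {"delta": 3.0, "theta": 4.0, "alpha": 5.0, "beta": 17.0}
        dens = {
            k: band_power(out[k][0], fs, 0.5, 99) / widths[k] for k in widths
        }
        vals = np.array(list(dens.values()))
        assert vals.max() / vals.min() < 1.2

    def test_band_above_nyquist_rejected(self):
        from eegemo.timefreq import BandDefinition

        rec = self._recording(np.zeros(100), fs=50.0)
        with pytest.raises(ValueError):
            bandpass_decompose(rec, [BandDefinition("hi", 10.0, 30.0)])


class TestRendering:
    def _scalogram(self, coeffs):
        from eegemo.timefreq import Scalogram

        n_s, n_t = coeffs.shape
        return Scalogram(
            coeffs, np.arange(1, n_s + 1, dtype=float), np.arange(n_t), WaveletSpec(), n_t
        )

    def test_zero_coefficients_render_constant_minimum_color(self):
        im = render_scalogram_image(self._scalogram(np.zeros((8, 32), complex)))
        assert np.all(im.pixels.reshape(-1, 3) == im.pixels[0, 0])
        import matplotlib

        lowest = np.round(np.array(matplotlib.colormaps["jet"](0.0)[:3]) * 255)
        np.testing.assert_array_equal(im.pixels[0, 0], lowest.astype(np.uint8))

    def test_rendering_is_deterministic(self):
        rng = np.random.default_rng(6)
        coeffs = rng.normal(size=(16, 64)) + 1j * rng.normal(size=(16, 64))
        a = render_scalogram_image(self._scalogram(coeffs))
        b = render_scalogram_image(self._scalogram(coeffs))
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_dominant_ridge_row_preserved_at_native_size(self):
        coeffs = np.full((12, 40), 0.05, dtype=complex)
        coeffs[7] = 3.0
        im = render_scalogram_image(
            self._scalogram(coeffs), size=(12, 40), colormap="gray"
        )
        row_intensity = im.pixels.mean(axis=(1, 2))
        assert int(np.argmax(row_intensity)) == 7

    def test_unknown_colormap_rejected(self):
        with pytest.raises(ValueError):
            render_scalogram_image(
                self._scalogram(np.ones((4, 8), complex)), colormap="no-such-map"
            )


class TestSegmentation:
    def _recording(self, n):
        return EEGRecording(np.arange(2 * n, dtype=float).reshape(2, n), 200.0, 2, 3, 4)

    def test_exact_window_gives_single_segment(self):
        segs = segment_signal(self._recording(1000), window_len=1000)
        assert len(segs) == 1
        assert segs[0].label == 2 and segs[0].subject_id == 3

    def test_non_overlapping_partition(self):
        rec = self._recording(3000)
        segs = segment_signal(rec, window_len=1000, hop=1000)
        assert len(segs) == 3
        np.testing.assert_array_equal(
            np.concatenate([s.samples for s in segs], axis=1), rec.samples
        )

    def test_bad_hop_and_window(self):
        with pytest.raises(ValueError):
            segment_signal(self._recording(100), window_len=50, hop=0)
        with pytest.raises(ValueError):
            segment_signal(self._recording(100), window_len=200)
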