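"""Time-frequency decomposition of 1-D EEG signals.

Provides the short-time Fourier transform, the continuous wavelet
transform (CWT) and its inverse, numerical admissibility checking,
canonical EEG band-pass decomposition, scalogram-image rendering for the
feature extractor, and fixed-length windowing.

Conventions
-----------
The CWT of a discrete signal :math:`u[t]` at scale :math:`m` (in samples)
and shift :math:`n` is the Riemann sum

.. math:: W(m, n) = \\frac{1}{m^r} \\sum_t u[t]\\,
          \\psi^*\\!\\Big(\\frac{t - n}{m}\\Big),

with :math:`r = 1/2` under L2 normalization (default, preserves the energy
of each daughter wavelet) or :math:`r = 1` under L1 (preserves peak
amplitude across scales; the convention used for synthesis).  The fast
path evaluates the sum by FFT convolution; a brute-force double loop over
``(scale, shift)`` lives in the test suite as the independent oracle.

Scales map to equivalent frequencies through the wavelet's spectral peak
:math:`\\omega_p`: ``f = peak_omega * fs / (2 pi m)``.

Wavelet families
----------------
* ``morse`` — generalized Morse wavelet, :math:`\\hat\\psi(\\omega) =
  a\\,\\omega^\\beta e^{-\\omega^\\gamma}` for :math:`\\omega > 0`
  (default gamma=3, beta=20); exactly analytic, exactly zero-mean.
* ``morlet`` — analytic Morlet with the zero-mean correction term,
  closed form in both domains (default omega0=6).
* ``gaussian`` — a non-oscillatory Gaussian bump.  It is *not* admissible
  (nonzero mean) and exists so the admissibility guard has a true
  negative to reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy import signal as sps

from .core import EEGRecording

__all__ = [
    "WindowSpec",
    "WaveletSpec",
    "Scalogram",
    "SpectrogramImage",
    "BandDefinition",
    "AdmissibilityError",
    "default_bands",
    "default_scales",
    "stft",
    "cwt",
    "icwt",
    "admissibility_constant",
    "bandpass_decompose",
    "render_scalogram_image",
    "segment_signal",
]


class AdmissibilityError(ValueError):
    """The wavelet violates the admissibility condition (nonzero mean)."""


# ---------------------------------------------------------------------------
# Windows and wavelets
# ---------------------------------------------------------------------------

_WINDOW_KINDS = ("rectangular", "hann", "gaussian")


@dataclass(frozen=True)
class WindowSpec:
    """Finite analysis window for the STFT."""

    kind: str = "hann"
    length: int = 128

    def __post_init__(self):
        if self.kind not in _WINDOW_KINDS:
            raise ValueError(f"unknown window kind {self.kind!r}")
        if self.length <= 0:
            raise ValueError("window length must be positive")

    def array(self) -> np.ndarray:
        if self.kind == "rectangular":
            return np.ones(self.length)
        if self.kind == "hann":
            return sps.windows.hann(self.length, sym=True)
        return sps.windows.gaussian(self.length, std=self.length / 6.0, sym=True)


_FAMILIES = ("morse", "morlet", "gaussian")
_NORMS = ("L1", "L2")


@dataclass(frozen=True)
class WaveletSpec:
    """Mother wavelet choice plus its shape parameters.

    ``gamma``/``beta`` apply to the Morse family, ``omega0`` to Morlet.
    ``amplitude`` is a global multiplier (the admissibility constant is
    quadratic in it).
    """

    family: str = "morse"
    gamma: float = 3.0
    beta: float = 20.0
    omega0: float = 6.0
    normalization: str = "L2"
    amplitude: float = 1.0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown wavelet family {self.family!r}")
        if self.normalization not in _NORMS:
            raise ValueError(f"normalization must be one of {_NORMS}")
        if self.family == "morse" and (self.gamma <= 0 or self.beta <= 0):
            raise ValueError("morse parameters gamma, beta must be positive")

    # -- frequency domain ---------------------------------------------------
    @property
    def peak_omega(self) -> float:
        """Angular frequency (rad/sample at scale 1) of the spectral peak."""
        if self.family == "morse":
            return (self.beta / self.gamma) ** (1.0 / self.gamma)
        if self.family == "morlet":
            return self.omega0
        return 0.0  # gaussian bump peaks at DC

    def freq_domain(self, omega) -> np.ndarray:
        """:math:`\\hat\\psi(\\omega)` of the mother wavelet."""
        w = np.asarray(omega, dtype=float)
        if self.family == "morse":
            a = 2.0 * (np.e * self.gamma / self.beta) ** (self.beta / self.gamma)
            out = np.zeros_like(w)
            pos = w > 0
            out[pos] = a * w[pos] ** self.beta * np.exp(-(w[pos] ** self.gamma))
        elif self.family == "morlet":
            c = np.pi ** -0.25 * np.sqrt(2 * np.pi)
            kappa = np.exp(-0.5 * self.omega0**2)
            out = c * (
                np.exp(-0.5 * (w - self.omega0) ** 2)
                - kappa * np.exp(-0.5 * w**2)
            )
        else:  # gaussian
            out = np.sqrt(2 * np.pi) * np.exp(-0.5 * w**2)
        return self.amplitude * out

    # -- time domain --------------------------------------------------------
    def time_domain(self, t) -> np.ndarray:
        """:math:`\\psi(t)` of the mother wavelet (complex for the
        oscillatory families)."""
        t = np.asarray(t, dtype=float)
        if self.family == "morlet":
            kappa = np.exp(-0.5 * self.omega0**2)
            out = (
                np.pi ** -0.25
                * (np.exp(1j * self.omega0 * t) - kappa)
                * np.exp(-0.5 * t**2)
            )
        elif self.family == "gaussian":
            out = np.exp(-0.5 * t**2).astype(complex)
        else:
            out = self._morse_time(t)
        return self.amplitude * out

    def _morse_time(self, t: np.ndarray) -> np.ndarray:
        # Inverse Fourier integral over the one-sided spectrum,
        # psi(t) = (1/2pi) int_0^inf psi_hat(w) e^{iwt} dw.  Evaluated once
        # by trapezoid quadrature on a dense time grid and cached as a
        # cubic spline; |t| beyond the effective support maps to 0.
        key = (self.gamma, self.beta)
        spline = _MORSE_SPLINE_CACHE.get(key)
        if spline is None:
            from scipy.interpolate import CubicSpline

            half = self.support_radius
            w_max = self._morse_cutoff()
            dw = w_max / 8192
            dt = 0.01
            nfft = int(2 ** np.ceil(np.log2(2 * np.pi / (dt * dw))))
            dt = 2 * np.pi / (nfft * dw)  # exact grid step after rounding
            spec = self.freq_domain(np.arange(nfft) * dw) / self.amplitude
            vals_all = np.fft.ifft(spec) * (nfft * dw / (2 * np.pi))
            n_half = int(np.ceil(half / dt))
            grid = np.arange(-n_half, n_half + 1) * dt
            vals = np.concatenate([vals_all[-n_half:], vals_all[: n_half + 1]])
            spline = CubicSpline(grid, vals, extrapolate=False)
            _MORSE_SPLINE_CACHE[key] = spline
        out = spline(t)
        return np.where(np.isnan(out), 0.0, out)

    def _morse_cutoff(self) -> float:
        w = self.peak_omega
        peak = w**self.beta * np.exp(-(w**self.gamma))
        hi = w
        while hi**self.beta * np.exp(-(hi**self.gamma)) > 1e-18 * peak:
            hi *= 1.25
        return hi

    @property
    def support_radius(self) -> float:
        """Half-width, in scale units, beyond which |psi| is negligible
        (< ~1e-12 of its peak) for the oscillatory families."""
        if self.family == "morlet":
            return 9.0
        if self.family == "morse":
            # effective Gaussian-like core of width ~ sqrt(beta*gamma)/peak
            return 7.0 * np.sqrt(self.beta * self.gamma) / self.peak_omega + 2.0
        return 9.0

    def check_admissible(self) -> None:
        """Cheap guard: an admissible wavelet has zero mean,
        i.e. :math:`\\hat\\psi(0) = 0`."""
        at_zero = abs(float(self.freq_domain(np.array(0.0))))
        at_peak = abs(float(self.freq_domain(np.array(max(self.peak_omega, 1e-3)))))
        if at_zero > 1e-8 * max(at_peak, 1e-300):
            raise AdmissibilityError(
                f"{self.family} wavelet has nonzero mean (psi_hat(0) = {at_zero:g}); "
                "the admissibility integral diverges"
            )


def default_scales(
    wavelet: WaveletSpec,
    sampling_rate: float,
    n_scales: int = 64,
    f_min: float = 1.0,
    f_max: float = 45.0,
) -> np.ndarray:
    """Logarithmically spaced scales covering ``f_min``–``f_max`` Hz.

    Returned strictly increasing (large scale = low frequency last... no:
    increasing scale means decreasing frequency, so the first row of the
    scalogram is the highest equivalent frequency).
    """
    if not 0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    freqs = np.geomspace(f_max, f_min, n_scales)
    return wavelet.peak_omega * sampling_rate / (2 * np.pi * freqs)


def scales_to_frequencies(wavelet: WaveletSpec, scales, sampling_rate: float) -> np.ndarray:
    """Equivalent frequency (Hz) of each scale."""
    return wavelet.peak_omega * sampling_rate / (2 * np.pi * np.asarray(scales, float))


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class Scalogram:
    """Complex CWT coefficient matrix, shape (n_scales, n_times)."""

    coefficients: np.ndarray
    scales: np.ndarray
    times: np.ndarray
    wavelet: WaveletSpec
    source_length: int
    boundary: str = "symmetric"

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients)
        self.scales = np.asarray(self.scales, dtype=float)
        self.times = np.asarray(self.times)
        if self.coefficients.shape != (len(self.scales), len(self.times)):
            raise ValueError("coefficient matrix shape must be (n_scales, n_times)")
        if np.any(self.scales <= 0) or np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be positive and strictly increasing")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.coefficients)


@dataclass
class SpectrogramImage:
    """Rendered 3-channel scalogram image with pixel values in [0, 255]."""

    pixels: np.ndarray
    colormap: str = "jet"
    scaling: str = "log"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be (H, W, 3)")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError("need 0 < low < high")


def default_bands() -> list[BandDefinition]:
    """The four canonical EEG bands: delta, theta, alpha, beta."""
    return [
        BandDefinition("delta", 1.0, 4.0),
        BandDefinition("theta", 4.0, 8.0),
        BandDefinition("alpha", 8.0, 13.0),
        BandDefinition("beta", 13.0, 30.0),
    ]


# ---------------------------------------------------------------------------
# STFT
# ---------------------------------------------------------------------------


def stft(signal, window: WindowSpec, hop: int, nfft: int | None = None):
    """Short-time Fourier transform.

    The transform of window position ``c`` (segment starting at
    ``c * hop``) is the one-sided DFT of the windowed segment with the
    complex phase referenced to absolute sample time, i.e.
    ``X[k, c] = sum_t x[t] w[t - c*hop] exp(-2j pi k t / nfft)``.

    Returns ``(freq_bins, window_starts, X)`` where ``X`` has frequencies
    along rows and window positions along columns.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D array")
    if hop <= 0:
        raise ValueError("hop must be positive")
    L = window.length
    if L > x.size:
        raise ValueError("window longer than signal")
    nfft = nfft or L
    w = window.array()
    starts = np.arange(0, x.size - L + 1, hop)
    n_bins = nfft // 2 + 1
    X = np.empty((n_bins, len(starts)), dtype=complex)
    k = np.arange(n_bins)
    for c, s in enumerate(starts):
        seg = x[s : s + L] * w
        X[:, c] = np.fft.rfft(seg, n=nfft) * np.exp(-2j * np.pi * k * s / nfft)
    freqs = k / nfft
    return freqs, starts, X


# ---------------------------------------------------------------------------
# CWT / ICWT
# ---------------------------------------------------------------------------

_BANK_CACHE: dict[tuple, list[np.ndarray]] = {}
_MORSE_SPLINE_CACHE: dict[tuple, object] = {}
_PLAN_CACHE: dict[tuple, np.ndarray] = {}


def _daughter_bank(wavelet: WaveletSpec, scales: tuple[float, ...]) -> list[np.ndarray]:
    """Sampled daughter wavelets psi(d / m) for d in [-T, T] (no
    normalization prefactor), cached per (wavelet, scales)."""
    key = (wavelet, scales)
    bank = _BANK_CACHE.get(key)
    if bank is None:
        bank = []
        for m in scales:
            T = max(1, int(np.ceil(wavelet.support_radius * m)))
            d = np.arange(-T, T + 1)
            bank.append(wavelet.time_domain(d / m))
        _BANK_CACHE[key] = bank
    return bank


def daughter_wavelet(wavelet: WaveletSpec, scale: float, shift: float, t) -> np.ndarray:
    """Normalized daughter wavelet psi_{m,n}(t) = psi((t - n)/m) / m^r."""
    t = np.asarray(t, dtype=float)
    r = 0.5 if wavelet.normalization == "L2" else 1.0
    return wavelet.time_domain((t - shift) / scale) / scale**r


def cwt(signal, wavelet: WaveletSpec, scales, boundary: str = "symmetric") -> Scalogram:
    """Continuous wavelet transform of a 1-D signal.

    ``boundary='symmetric'`` mirror-pads the signal by one maximum wavelet
    support (capped at the signal length) to suppress edge artifacts in
    rendered scalograms; ``'zero'`` treats the signal as zero outside its
    domain, matching the defining integral literally.
    """
    u = np.asarray(signal, dtype=float)
    if u.ndim != 1 or u.size == 0:
        raise ValueError("signal must be a non-empty 1-D array")
    scales = np.atleast_1d(np.asarray(scales, dtype=float))
    if scales.size == 0:
        raise ValueError("at least one scale is required")
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    if boundary not in ("symmetric", "zero"):
        raise ValueError("boundary must be 'symmetric' or 'zero'")
    wavelet.check_admissible()

    bank = _daughter_bank(wavelet, tuple(scales))
    N = u.size
    pad = 0
    if boundary == "symmetric":
        max_T = max((len(b) - 1) // 2 for b in bank)
        pad = min(N, max_T)
        u = np.pad(u, pad, mode="symmetric")

    # Batched FFT correlation: W[j, n] = sum_d u[n + d] conj(psi_j(d/m_j))
    # / m_j^r.  All scales share one FFT length, so the daughter spectra
    # can be precomputed once per (wavelet, scales, length) and the whole
    # bank applied with a single vectorized inverse FFT.
    from scipy.fft import fft, ifft, next_fast_len

    r = 0.5 if wavelet.normalization == "L2" else 1.0
    max_len = max(len(b) for b in bank)
    L = next_fast_len(u.size + max_len - 1)
    key = (wavelet, tuple(scales), L)
    plan = _PLAN_CACHE.get(key)
    if plan is None:
        H = np.zeros((scales.size, L), dtype=complex)
        for j, psi in enumerate(bank):
            H[j, : len(psi)] = np.conj(psi)[::-1]
        plan = np.asarray(fft(H, axis=1))
        _PLAN_CACHE[key] = plan
    U = fft(u, n=L)
    conv = ifft(U[None, :] * plan, axis=1)
    coeffs = np.empty((scales.size, N), dtype=complex)
    for j, (m, psi) in enumerate(zip(scales, bank)):
        T = (len(psi) - 1) // 2
        coeffs[j] = conv[j, T + pad : T + pad + N] / m**r
    return Scalogram(coeffs, scales, np.arange(N), wavelet, N, boundary=boundary)


def admissibility_constant(wavelet: WaveletSpec) -> float:
    """Admissibility constant :math:`C_\\psi = \\int |\\hat\\psi(\\omega)|^2
    / |\\omega|\\, d\\omega`, by adaptive quadrature.

    Finite and positive for zero-mean wavelets; raises
    :class:`AdmissibilityError` when :math:`\\hat\\psi(0) \\ne 0` (the
    integral diverges logarithmically).
    """
    wavelet.check_admissible()

    def integrand(w):
        pos = wavelet.freq_domain(np.array(w))
        neg = wavelet.freq_domain(np.array(-w))
        return (abs(pos) ** 2 + abs(neg) ** 2) / w

    peak = max(wavelet.peak_omega, 1.0)
    val1, _ = integrate.quad(integrand, 0.0, peak, limit=200)
    val2, _ = integrate.quad(integrand, peak, np.inf, limit=200)
    c = val1 + val2
    if not np.isfinite(c) or c <= 0:
        raise AdmissibilityError(f"admissibility integral did not converge (C = {c})")
    return float(c)


def icwt(scalogram: Scalogram) -> np.ndarray:
    """Inverse CWT: reconstruct the real signal from its coefficients.

    Implements the double-integral synthesis formula as a discrete sum
    over the (log-spaced) scale grid and all shifts,

    .. math:: u(t) \\approx \\frac{2}{C_\\psi} \\mathrm{Re} \\sum_j
              \\Delta(\\ln m_j) \\sum_n W_{L1}(m_j, n)\\,
              \\frac{1}{m_j} \\psi\\Big(\\frac{t-n}{m_j}\\Big),

    where :math:`W_{L1}` are the L1-normalized coefficients and the
    :math:`dm/m^2` measure of the continuous formula becomes
    :math:`d(\\ln m)` once one :math:`1/m` is absorbed into each of the
    analysis and synthesis kernels.  Accurate when the scale grid densely
    covers the signal's band.
    """
    wavelet = scalogram.wavelet
    c_psi = admissibility_constant(wavelet)
    scales = scalogram.scales
    W = scalogram.coefficients
    if wavelet.normalization == "L2":
        W = W / np.sqrt(scales)[:, None]  # convert to L1 convention
    if len(scales) > 1:
        dln = np.gradient(np.log(scales))
    else:
        dln = np.array([1.0])
    N = W.shape[1]
    bank = _daughter_bank(wavelet, tuple(scales))
    mirror = getattr(scalogram, "boundary", "symmetric") == "symmetric"
    recon = np.zeros(N, dtype=complex)
    for j, (m, psi) in enumerate(zip(scales, bank)):
        T = (len(psi) - 1) // 2
        row = W[j]
        pad = 0
        if mirror:
            # Extend shifts past the edges consistently with the forward
            # transform's mirrored signal.  For a wavelet with a real
            # spectrum, psi(-t) = conj(psi(t)), so the coefficients of the
            # mirrored signal are the conjugated reflection of the rows.
            pad = min(N, T)
            row = np.pad(row, pad, mode="symmetric")
            row[:pad] = np.conj(row[:pad])
            row[-pad:] = np.conj(row[-pad:]) if pad else row[-pad:]
        contrib = sps.fftconvolve(row, psi, mode="full")[T + pad : T + pad + N]
        recon += dln[j] * contrib / m
    return (2.0 / c_psi) * recon.real


# ---------------------------------------------------------------------------
# Band decomposition, rendering, segmentation
# ---------------------------------------------------------------------------


def bandpass_decompose(
    recording: EEGRecording, bands: list[BandDefinition] | None = None
) -> dict[str, np.ndarray]:
    """Zero-phase 4th-order Butterworth band-pass per band per channel.

    Returns a mapping band name -> (n_channels, n_samples) array.
    """
    if bands is None:
        bands = default_bands()
    fs = recording.sampling_rate
    out = {}
    for band in bands:
        if band.high >= fs / 2:
            raise ValueError(
                f"band {band.name} upper edge {band.high} Hz at/above Nyquist ({fs / 2} Hz)"
            )
        sos = sps.butter(4, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
        out[band.name] = sps.sosfiltfilt(sos, recording.samples, axis=1)
    return out


def render_scalogram_image(
    scalogram: Scalogram,
    size: tuple[int, int] = (224, 224),
    colormap: str = "jet",
    scaling: str = "log",
) -> SpectrogramImage:
    """Map |coefficients| through an amplitude scaling and a colormap and
    resize bilinearly to ``size`` (the backbone input resolution).

    Deterministic: identical scalograms yield identical pixel buffers.
    """
    import matplotlib

    from skimage.transform import resize

    if scaling not in ("linear", "log"):
        raise ValueError("scaling must be 'linear' or 'log'")
    try:
        cmap = matplotlib.colormaps[colormap]
    except KeyError as exc:
        raise ValueError(f"unknown colormap {colormap!r}") from exc
    mag = scalogram.magnitude
    if mag.size == 0:
        raise ValueError("empty scalogram")
    x = np.log1p(mag) if scaling == "log" else mag
    lo, hi = float(x.min()), float(x.max())
    norm = (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)
    # resize the scaled magnitude first, then look up colors: value
    # interpolation avoids mixing unrelated colormap entries at edges
    resized = resize(norm, size, order=1, mode="edge", anti_aliasing=False,
                     preserve_range=True)
    rgb = cmap(np.clip(resized, 0.0, 1.0))[:, :, :3]
    pixels = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    return SpectrogramImage(pixels, colormap=colormap, scaling=scaling)


def segment_signal(
    recording: EEGRecording, window_len: int = 1000, hop: int | None = None
) -> list[EEGRecording]:
    """Split a recording into fixed-length analysis windows.

    Segments inherit the parent's label and identifiers; the count is
    ``floor((n_samples - window_len) / hop) + 1``.
    """
    if hop is None:
        hop = window_len
    if hop <= 0:
        raise ValueError("hop must be positive")
    if window_len > recording.n_samples:
        raise ValueError("window_len exceeds recording length")
    segments = []
    for start in range(0, recording.n_samples - window_len + 1, hop):
        segments.append(
            EEGRecording(
                samples=recording.samples[:, start : start + window_len].copy(),
                sampling_rate=recording.sampling_rate,
                label=recording.label,
                subject_id=recording.subject_id,
                trial_id=recording.trial_id,
                channel_names=recording.channel_names,
            )
        )
    return segments
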