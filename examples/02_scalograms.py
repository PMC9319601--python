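"""Wavelet analysis of one EEG channel: scalogram, admissibility, and
round-trip reconstruction through the inverse transform.

A band-limited test signal is analysed with the generalized Morse
wavelet (gamma=3, beta=20) on 64 log-spaced scales covering 1-45 Hz; the
inverse transform should reproduce it to within a few percent.
"""

import numpy as np

from eegemo import (
    WaveletSpec,
    admissibility_constant,
    cwt,
    default_scales,
    icwt,
    render_scalogram_image,
)
from eegemo.timefreq import scales_to_frequencies

fs, n = 200.0, 1000
t = np.arange(n) / fs
signal = np.sin(2 * np.pi * 7 * t) + 0.6 * np.sin(2 * np.pi * 21 * t + 0.8)

for family in ("morse", "morlet"):
    wavelet = WaveletSpec(family=family)
    c_psi = admissibility_constant(wavelet)
    scales = default_scales(wavelet, fs)
    scalogram = cwt(signal, wavelet, scales)
    freqs = scales_to_frequencies(wavelet, scales, fs)
    ridge = freqs[np.argmax(np.abs(scalogram.coefficients).mean(axis=1))]
    recon = icwt(scalogram)
    err = np.linalg.norm(recon - signal) / np.linalg.norm(signal)
    image = render_scalogram_image(scalogram)
    print(f"{family:7s} C_psi={c_psi:6.4f}  dominant ridge ~{ridge:5.1f} Hz  "
          f"icwt relative L2 error {err:.4f}  image {image.pixels.shape}")

# C_psi finite and positive certifies admissibility; the ridge sits near
# the stronger 7 Hz component; the reconstruction error stays below 0.05.
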