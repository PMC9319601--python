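"""Shared fixtures: small montages, synthetic specs, and a band-power
oracle based on Welch periodograms (independent of the wavelet path)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from eegemo.core import ChannelMontage
from eegemo.features import FeatureMatrix
from eegemo.synth import SyntheticDatasetSpec


def band_power(x: np.ndarray, fs: float, low: float, high: float) -> float:
    """Welch periodogram power of ``x`` inside [low, high) Hz — the
    independent oracle for any band-power claim."""
    f, p = sps.welch(x, fs=fs, nperseg=min(len(x), 512))
    mask = (f >= low) & (f < high)
    return float(np.trapezoid(p[mask], f[mask]))


@pytest.fixture
def small_montage() -> ChannelMontage:
    """8 channels, informative subset scattered at (1, 3, 4, 6)."""
    return ChannelMontage(tuple(f"ch{i:02d}" for i in range(8)), (1, 3, 4, 6))


@pytest.fixture
def small_spec(small_montage) -> SyntheticDatasetSpec:
    """2 subjects x 3 trials/class on the 8-channel montage."""
    return SyntheticDatasetSpec(
        n_subjects=2,
        n_trials_per_class=3,
        montage=small_montage,
        seed=7,
    ).with_beta_contrast(2.0)


def toy_feature_matrix(values: np.ndarray, channels, labels) -> FeatureMatrix:
    """Assemble a FeatureMatrix from per-(recording, channel) rows.

    ``values`` is (n_recordings * n_channels, q) ordered recording-major.
    """
    n_ch = len(channels)
    n_rec = values.shape[0] // n_ch
    meta = pd.DataFrame(
        {
            "recording": np.repeat(np.arange(n_rec), n_ch),
            "subject": 0,
            "trial": np.repeat(np.arange(n_rec), n_ch),
            "channel": list(channels) * n_rec,
            "label": np.repeat(np.asarray(labels), n_ch),
        }
    )
    return FeatureMatrix(values, meta)
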