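"""Feature extraction from scalogram images.

The framework treats the image-to-vector step as a pluggable contract so
that a pretrained CNN backbone (GoogleNet-style, output dimension 1000)
can be dropped in where available, while the bundled deterministic
grid-statistics extractor keeps the whole pipeline runnable and testable
with zero downloads.  Layer-arithmetic helpers (convolution output size)
and the softmax cross-entropy loss used when such a backbone is trained
are implemented here as plain functions.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timefreq import SpectrogramImage

__all__ = [
    "ConvLayerSpec",
    "conv_output_size",
    "InfiniteLossError",
    "cross_entropy_loss",
    "FeatureExtractor",
    "GridStatsExtractor",
    "fallback_extractor",
    "register_extractor",
    "get_extractor",
    "available_extractors",
    "FeatureMatrix",
    "extract_features",
]


# ---------------------------------------------------------------------------
# Layer arithmetic and loss
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConvLayerSpec:
    """Geometry of one square convolution layer (sizes in pixels)."""

    y_in: int
    kernel: int
    stride: int
    padding: int = 0

    def __post_init__(self):
        if min(self.y_in, self.kernel, self.stride) <= 0 or self.padding < 0:
            raise ValueError("sizes must be positive (padding may be 0)")


def conv_output_size(spec: ConvLayerSpec) -> int:
    """Output size of a convolution layer:
    ``(y_in + 2*padding - kernel) / stride + 1``.

    Raises if the division is not exact (the layer geometry would not
    tile the input).
    """
    num = spec.y_in + 2 * spec.padding - spec.kernel
    if num < 0:
        raise ValueError("kernel larger than padded input")
    if num % spec.stride != 0:
        raise ValueError(
            f"layer geometry mismatch: ({spec.y_in} + 2*{spec.padding} - "
            f"{spec.kernel}) not divisible by stride {spec.stride}"
        )
    return num // spec.stride + 1


class InfiniteLossError(ValueError):
    """The predicted probability of the true class is zero."""


def cross_entropy_loss(true_onehot, predicted_probs) -> float:
    """Softmax cross-entropy ``-sum_i r_i * ln(delta_i)`` (natural log).

    ``true_onehot`` must be a one-hot vector and ``predicted_probs`` a
    probability vector (entries in [0, 1], summing to 1).  Zero iff the
    true class receives probability 1; a zero probability at the true
    class raises :class:`InfiniteLossError`.
    """
    r = np.asarray(true_onehot, dtype=float)
    d = np.asarray(predicted_probs, dtype=float)
    if r.shape != d.shape or r.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if not (np.all((r == 0) | (r == 1)) and r.sum() == 1):
        raise ValueError("true_onehot must be one-hot")
    if np.any(d < 0) or np.any(d > 1) or abs(d.sum() - 1.0) > 1e-9:
        raise ValueError("predicted_probs must be a probability vector")
    p_true = float(d[np.argmax(r)])
    if p_true == 0.0:
        raise InfiniteLossError("true class has predicted probability 0")
    return -math.log(p_true)


# ---------------------------------------------------------------------------
# Extractor contract
# ---------------------------------------------------------------------------


class FeatureExtractor(ABC):
    """Contract for image -> fixed-length feature vector extractors.

    Implementations must be deterministic, produce finite values, and keep
    ``output_dim`` constant across inputs.
    """

    name: str = "abstract"
    output_dim: int = 0

    @abstractmethod
    def extract(self, image: SpectrogramImage) -> np.ndarray:
        """Return a 1-D float vector of length ``output_dim``."""

    @property
    def feature_names(self) -> list[str]:
        return [f"{self.name}_{i}" for i in range(self.output_dim)]


_EXTRACTOR_REGISTRY: dict[str, type[FeatureExtractor]] = {}


def register_extractor(cls: type[FeatureExtractor]) -> type[FeatureExtractor]:
    """Register an extractor class under ``cls.name`` (decorator-friendly).

    Backbone adapters (pretrained CNNs) plug in through this hook without
    becoming install-time dependencies.
    """
    _EXTRACTOR_REGISTRY[cls.name] = cls
    return cls


def get_extractor(name: str, **kwargs) -> FeatureExtractor:
    try:
        return _EXTRACTOR_REGISTRY[name](**kwargs)
    except KeyError:
        raise KeyError(
            f"no extractor named {name!r}; available: {sorted(_EXTRACTOR_REGISTRY)}"
        ) from None


def available_extractors() -> list[str]:
    return sorted(_EXTRACTOR_REGISTRY)


@register_extractor
class GridStatsExtractor(FeatureExtractor):
    """Deterministic multi-scale grid-statistics extractor.

    The image is converted to grayscale and divided into 1x1, 2x2, 4x4 and
    8x8 grids (85 cells).  Each cell contributes its intensity mean, its
    intensity variance, and an 8-bin gradient-orientation histogram
    (magnitude-weighted), giving 850 features, zero-padded to the
    conventional backbone width of 1000.

    By construction the mean features respond to overall brightness while
    the orientation histograms are insensitive to constant brightness
    shifts (up to round-off in bin assignment), which makes the feature
    groups individually interpretable.
    """

    name = "grid-stats"
    output_dim = 1000
    grid_levels = (1, 2, 4, 8)
    n_orient_bins = 8

    def extract(self, image: SpectrogramImage) -> np.ndarray:
        gray = image.pixels.mean(axis=2) / 255.0
        gy, gx = np.gradient(gray)
        mag = np.hypot(gx, gy)
        ang = np.mod(np.arctan2(gy, gx), 2 * np.pi)
        bins = np.minimum(
            (ang / (2 * np.pi) * self.n_orient_bins).astype(int),
            self.n_orient_bins - 1,
        )
        means, variances, orients = [], [], []
        for g in self.grid_levels:
            row_edges = np.linspace(0, gray.shape[0], g + 1).astype(int)
            col_edges = np.linspace(0, gray.shape[1], g + 1).astype(int)
            for i in range(g):
                for j in range(g):
                    cell = gray[row_edges[i]:row_edges[i + 1],
                                col_edges[j]:col_edges[j + 1]]
                    means.append(cell.mean())
                    variances.append(cell.var())
                    cb = bins[row_edges[i]:row_edges[i + 1],
                              col_edges[j]:col_edges[j + 1]]
                    cm = mag[row_edges[i]:row_edges[i + 1],
                             col_edges[j]:col_edges[j + 1]]
                    hist = np.bincount(
                        cb.ravel(), weights=cm.ravel(), minlength=self.n_orient_bins
                    )
                    orients.extend(hist)
        vec = np.concatenate([means, variances, orients])
        if vec.size > self.output_dim:
            vec = vec[: self.output_dim]
        elif vec.size < self.output_dim:
            vec = np.pad(vec, (0, self.output_dim - vec.size))
        return vec.astype(float)

    @property
    def feature_names(self) -> list[str]:
        names = []
        cells = [(g, i, j) for g in self.grid_levels for i in range(g) for j in range(g)]
        for stat in ("mean", "var"):
            names += [f"g{g}_r{i}c{j}_{stat}" for g, i, j in cells]
        for g, i, j in cells:
            names += [f"g{g}_r{i}c{j}_ori{b}" for b in range(self.n_orient_bins)]
        names += [f"pad{i}" for i in range(self.output_dim - len(names))]
        return names


def fallback_extractor() -> FeatureExtractor:
    """The bundled no-download extractor (grid statistics, q = 1000)."""
    return GridStatsExtractor()


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """p x q matrix of per-(recording, channel) feature vectors.

    ``meta`` carries one row per matrix row with columns
    ``(recording, subject, trial, channel, label)``; ``channel`` holds the
    electrode name.
    """

    values: np.ndarray
    meta: pd.DataFrame
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (p, q)")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("meta must have one row per feature row")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.values.shape[1])]
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length mismatch")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> list[str]:
        """Channel names in first-appearance order."""
        return list(dict.fromkeys(self.meta["channel"]))

    def rows_for_channel(self, channel: str) -> np.ndarray:
        return np.flatnonzero((self.meta["channel"] == channel).to_numpy())

    def subset_channels(self, channels) -> "FeatureMatrix":
        keep = self.meta["channel"].isin(list(channels)).to_numpy()
        return FeatureMatrix(
            self.values[keep], self.meta.loc[keep], list(self.feature_names)
        )


def extract_features(images, extractor: FeatureExtractor, meta=None) -> FeatureMatrix:
    """Run an extractor over a list of images, preserving input order.

    ``meta`` (optional) is a sequence of dicts or a DataFrame aligned with
    ``images`` providing the (recording, subject, trial, channel, label)
    row metadata.
    """
    images = list(images)
    if not images:
        raise ValueError("no images to extract features from")
    shape0 = images[0].pixels.shape
    if any(im.pixels.shape != shape0 for im in images):
        raise ValueError("all images must share one size")
    rows = []
    for im in images:
        vec = np.asarray(extractor.extract(im), dtype=float).ravel()
        if vec.size != extractor.output_dim:
            raise ValueError(
                f"extractor {extractor.name!r} output length drifted: "
                f"{vec.size} != {extractor.output_dim}"
            )
        rows.append(vec)
    if meta is None:
        meta = pd.DataFrame(
            {
                "recording": range(len(images)),
                "subject": 0,
                "trial": 0,
                "channel": "ch00",
                "label": 0,
            }
        )
    elif not isinstance(meta, pd.DataFrame):
        meta = pd.DataFrame(list(meta))
    return FeatureMatrix(np.vstack(rows), meta, list(extractor.feature_names))
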