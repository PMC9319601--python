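"""Core domain types shared by every pipeline stage.

The data model mirrors a SEED-style emotion experiment: multiple subjects
watch emotion-evoking film clips while a 62-channel 10-20 EEG montage is
recorded; every trial carries one of three emotion labels (negative,
neutral, positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "EmotionClass",
    "ChannelMontage",
    "EEGRecording",
    "SEED_62_CHANNELS",
    "SEED_26_SUBSET",
]


class EmotionClass(IntEnum):
    """The three emotion labels, with fixed integer codes."""

    NEGATIVE = 0
    NEUTRAL = 1
    POSITIVE = 2

    @classmethod
    def from_any(cls, value) -> "EmotionClass":
        """Coerce an int code, a name string or an EmotionClass."""
        if isinstance(value, cls):
            return value
        if isinstance(value, (int, np.integer)):
            return cls(int(value))
        if isinstance(value, (str, bytes)):
            name = value.decode() if isinstance(value, bytes) else value
            return cls[name.strip().upper()]
        raise ValueError(f"cannot interpret emotion label {value!r}")


#: Extended 10-20 montage used by 62-channel emotion-EEG recordings.
SEED_62_CHANNELS: tuple[str, ...] = (
    "FP1", "FPZ", "FP2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "CB1", "O1", "OZ", "O2", "CB2",
)

#: Synthetic 26-channel working subset covering frontal, temporal, central
#: and parietal sites.  Emotion-EEG studies often analyse ~26 of the 62
#: electrodes without a canonical listing; this spread is our own choice.
SEED_26_SUBSET: tuple[str, ...] = (
    "FP1", "FP2", "F7", "F3", "FZ", "F4", "F8",
    "FT7", "FC3", "FCZ", "FC4", "FT8",
    "T7", "C3", "CZ", "C4", "T8",
    "TP7", "CP3", "CPZ", "CP4", "TP8",
    "P7", "P3", "PZ", "P4",
)


@dataclass(frozen=True)
class ChannelMontage:
    """An ordered electrode layout plus a working subset of channels.

    Parameters
    ----------
    channel_names
        Ordered, unique 10-20 electrode labels.
    selected_subset
        Strictly increasing indices into ``channel_names`` marking the
        working subset used when channel selection is fixed a priori.
    """

    channel_names: tuple[str, ...]
    selected_subset: tuple[int, ...] = ()

    def __post_init__(self):
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        sub = tuple(int(i) for i in self.selected_subset)
        object.__setattr__(self, "selected_subset", sub)
        if any(not 0 <= i < len(names) for i in sub):
            raise ValueError("selected_subset index out of range")
        if any(b <= a for a, b in zip(sub, sub[1:])):
            raise ValueError("selected_subset must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def subset_names(self) -> tuple[str, ...]:
        return tuple(self.channel_names[i] for i in self.selected_subset)

    @classmethod
    def seed62(cls) -> "ChannelMontage":
        """Full 62-channel montage with the 26-channel working subset."""
        idx = tuple(sorted(SEED_62_CHANNELS.index(c) for c in SEED_26_SUBSET))
        return cls(SEED_62_CHANNELS, idx)

    @classmethod
    def simple(cls, n_channels: int, n_selected: int | None = None) -> "ChannelMontage":
        """Small generic montage (``ch00``, ``ch01``, ...) for experiments."""
        names = tuple(f"ch{i:02d}" for i in range(n_channels))
        if n_selected is None:
            n_selected = n_channels
        return cls(names, tuple(range(n_selected)))


@dataclass
class EEGRecording:
    """One labelled multi-channel window of raw EEG.

    ``samples`` is (n_channels, n_samples) in microvolts; ``sampling_rate``
    in Hz.  ``subject_id`` / ``trial_id`` identify provenance.
    """

    samples: np.ndarray
    sampling_rate: float
    label: EmotionClass
    subject_id: int
    trial_id: int
    channel_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (n_channels, n_samples)")
        if self.samples.shape[1] == 0:
            raise ValueError("recording must contain at least one sample")
        if self.samples.shape[0] == 0:
            raise ValueError("recording must contain at least one channel")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        self.label = EmotionClass.from_any(self.label)
        if self.channel_names and len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length mismatch")
        self.channel_names = tuple(self.channel_names)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Window length in seconds."""
        return self.n_samples / self.sampling_rate
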