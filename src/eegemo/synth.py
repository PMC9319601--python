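"""Synthetic emotion-EEG generator.

Emulates the layout of a SEED-style experiment (subjects x trials x
channels x samples, three emotion labels) with a controllable band-power
signal model, so the full pipeline can be exercised and validated without
any external recording.

Signal model
------------
Each *informative* channel carries, per canonical EEG band (delta 1-4 Hz,
theta 4-8 Hz, alpha 8-13 Hz, beta 13-30 Hz), a small number of sinusoids at
random frequencies inside the band with random phases.  The amplitude of a
band's components is ``base_amplitude * class_band_gain[label][band]``
(optionally scaled by a per-subject lognormal factor), so the emotion label
manifests as a class-dependent band-power profile — the statistical
signature the downstream selection and classification stages are designed
to pick up.  Non-informative channels carry white Gaussian noise only;
informative channels add the same noise on top of the oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import ChannelMontage, EEGRecording, EmotionClass

__all__ = [
    "BAND_EDGES",
    "SyntheticDatasetSpec",
    "generate_recording",
    "generate_dataset",
    "write_dataset",
]

#: Canonical band edges in Hz, ordered (delta, theta, alpha, beta).
BAND_EDGES: tuple[tuple[float, float], ...] = ((1, 4), (4, 8), (8, 13), (13, 30))
BAND_NAMES: tuple[str, ...] = ("delta", "theta", "alpha", "beta")


def _default_gains() -> dict[EmotionClass, tuple[float, float, float, float]]:
    # Classes differ only in beta-band gain: positive 2x, negative 0.5x.
    return {
        EmotionClass.NEGATIVE: (1.0, 1.0, 1.0, 0.5),
        EmotionClass.NEUTRAL: (1.0, 1.0, 1.0, 1.0),
        EmotionClass.POSITIVE: (1.0, 1.0, 1.0, 2.0),
    }


@dataclass
class SyntheticDatasetSpec:
    """Parameters of one synthetic experiment.

    Defaults mirror a SEED-like session: 15 subjects, 15 clips (5 per
    emotion), 62-channel montage with a 26-channel working subset,
    1000-sample analysis windows.  A sampling rate of 200 Hz makes a
    window span 5 s and resolves every band up to beta (30 Hz).
    """

    n_subjects: int = 15
    n_trials_per_class: int = 5
    montage: ChannelMontage = field(default_factory=ChannelMontage.seed62)
    sampling_rate: float = 200.0
    n_samples: int = 1000
    class_band_gain: dict[EmotionClass, tuple[float, float, float, float]] = field(
        default_factory=_default_gains
    )
    informative_channels: tuple[int, ...] | None = None  # None -> montage subset
    base_amplitude: float = 1.0
    n_components_per_band: int = 3
    noise_sd: float = 1.0
    subject_effect_sd: float = 0.1  # lognormal sigma; 0 disables
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0 or self.n_trials_per_class <= 0:
            raise ValueError("subject and trial counts must be positive")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.informative_channels is None:
            self.informative_channels = tuple(self.montage.selected_subset)
        self.informative_channels = tuple(int(i) for i in self.informative_channels)
        n_ch = self.montage.n_channels
        if any(not 0 <= i < n_ch for i in self.informative_channels):
            raise ValueError("informative_channels outside montage")
        self.class_band_gain = {
            EmotionClass.from_any(k): tuple(float(g) for g in v)
            for k, v in self.class_band_gain.items()
        }
        for gains in self.class_band_gain.values():
            if len(gains) != len(BAND_EDGES):
                raise ValueError("one gain per band (delta, theta, alpha, beta)")
            if any(g <= 0 for g in gains):
                raise ValueError("band gains must be positive")

    def with_beta_contrast(self, factor: float) -> "SyntheticDatasetSpec":
        """Copy of the spec with the positive class' beta gain set to
        ``factor`` (neutral 1x, negative 1/factor), a convenient knob for
        separability experiments."""
        gains = {
            EmotionClass.NEGATIVE: (1.0, 1.0, 1.0, 1.0 / factor),
            EmotionClass.NEUTRAL: (1.0, 1.0, 1.0, 1.0),
            EmotionClass.POSITIVE: (1.0, 1.0, 1.0, float(factor)),
        }
        return replace(self, class_band_gain=gains)


def _recording_rng(spec: SyntheticDatasetSpec, subject_id: int, trial_id: int,
                   label: EmotionClass) -> np.random.Generator:
    # Stream keyed by (seed, subject, trial, label): records are identical
    # no matter the order in which they are generated.
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), int(subject_id), int(trial_id), int(label)])
    )


def _subject_multiplier(spec: SyntheticDatasetSpec, subject_id: int) -> float:
    if spec.subject_effect_sd <= 0:
        return 1.0
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 0x5EED, int(subject_id)])
    )
    return float(rng.lognormal(mean=0.0, sigma=spec.subject_effect_sd))


def generate_recording(spec: SyntheticDatasetSpec, label, subject_id: int,
                       trial_id: int) -> EEGRecording:
    """Generate one labelled multi-channel window.

    Deterministic given ``(spec.seed, subject_id, trial_id, label)``.
    """
    label = EmotionClass.from_any(label)
    if label not in spec.class_band_gain:
        raise ValueError(f"no band gains configured for label {label!r}")
    rng = _recording_rng(spec, subject_id, trial_id, label)
    n_ch, n_t = spec.montage.n_channels, spec.n_samples
    if n_ch == 0:
        raise ValueError("montage has no channels")
    t = np.arange(n_t) / spec.sampling_rate
    gains = spec.class_band_gain[label]
    subj_mult = _subject_multiplier(spec, subject_id)

    samples = np.zeros((n_ch, n_t))
    informative = set(spec.informative_channels)
    for ch in range(n_ch):
        if ch in informative:
            sig = np.zeros(n_t)
            for (low, high), gain in zip(BAND_EDGES, gains):
                freqs = rng.uniform(low, high, size=spec.n_components_per_band)
                phases = rng.uniform(0, 2 * np.pi, size=spec.n_components_per_band)
                amp = spec.base_amplitude * gain * subj_mult
                sig += amp * np.sin(
                    2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]
                ).sum(axis=0)
            samples[ch] = sig
    if spec.noise_sd > 0:
        samples += rng.normal(0.0, spec.noise_sd, size=(n_ch, n_t))
    return EEGRecording(
        samples=samples,
        sampling_rate=spec.sampling_rate,
        label=label,
        subject_id=int(subject_id),
        trial_id=int(trial_id),
        channel_names=spec.montage.channel_names,
    )


def generate_dataset(spec: SyntheticDatasetSpec) -> list[EEGRecording]:
    """Generate the full balanced dataset.

    Returns ``n_subjects * 3 * n_trials_per_class`` recordings; trial ids
    are unique within a subject, interleaved across classes in the fixed
    order (negative, neutral, positive) so labels are balanced.
    """
    recordings: list[EEGRecording] = []
    for subject in range(spec.n_subjects):
        trial = 0
        for rep in range(spec.n_trials_per_class):
            for label in EmotionClass:
                recordings.append(generate_recording(spec, label, subject, trial))
                trial += 1
    return recordings


def write_dataset(recordings, path, format: str = "hdf5") -> None:
    """Persist recordings to a ``.mat`` (MATLAB v7) or HDF5 container.

    Round-trips losslessly through :func:`eegemo.io.read_dataset`.
    """
    from . import io as _io  # local import: io depends on core only

    _io.write_dataset(recordings, path, format=format)
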