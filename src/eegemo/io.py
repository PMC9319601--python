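"""Readers/writers for EEG datasets in MATLAB-v7 ``.mat`` and HDF5 containers.

Both layouts mirror how SEED-style recordings are distributed:

* ``.mat``: one variable per recording (``rec0000`` ...) holding the
  (n_channels, n_samples) matrix, plus flat metadata arrays ``labels``,
  ``subjects``, ``trials``, ``fs`` and a ``channels`` name list.
* HDF5: groups ``/subject_<s>/trial_<t>`` each with a ``samples`` dataset
  and attrs ``label``, ``fs``, ``subject_id``, ``trial_id``; channel names
  as UTF-8 strings in a root attribute.
"""

from __future__ import annotations

import numpy as np

from .core import EEGRecording, EmotionClass

__all__ = ["write_dataset", "read_dataset"]

_FORMATS = ("mat", "hdf5")


class DatasetSchemaError(ValueError):
    """A container is missing a required field or holds unknown codes."""


def _check_format(format: str) -> str:
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    return format


def write_dataset(recordings, path, format: str = "hdf5") -> None:
    recordings = list(recordings)
    _check_format(format)
    if not recordings:
        raise ValueError("cannot write an empty dataset")
    if format == "mat":
        _write_mat(recordings, path)
    else:
        _write_hdf5(recordings, path)


def read_dataset(path, format: str = "hdf5") -> list[EEGRecording]:
    _check_format(format)
    if format == "mat":
        return _read_mat(path)
    return _read_hdf5(path)


def _write_mat(recordings: list[EEGRecording], path) -> None:
    from scipy.io import savemat

    out = {
        "labels": np.array([int(r.label) for r in recordings]),
        "subjects": np.array([r.subject_id for r in recordings]),
        "trials": np.array([r.trial_id for r in recordings]),
        "fs": np.array([r.sampling_rate for r in recordings]),
        "channels": np.array(list(recordings[0].channel_names), dtype=object),
    }
    for i, rec in enumerate(recordings):
        out[f"rec{i:04d}"] = rec.samples
    savemat(path, out)


def _read_mat(path) -> list[EEGRecording]:
    from scipy.io import loadmat

    raw = loadmat(path, squeeze_me=False)
    for key in ("labels", "subjects", "trials", "fs"):
        if key not in raw:
            raise DatasetSchemaError(f"mat container missing variable {key!r}")
    labels = np.atleast_1d(np.squeeze(raw["labels"]))
    subjects = np.atleast_1d(np.squeeze(raw["subjects"]))
    trials = np.atleast_1d(np.squeeze(raw["trials"]))
    fs = np.atleast_1d(np.squeeze(raw["fs"]))
    channels: tuple[str, ...] = ()
    if "channels" in raw:
        channels = tuple(str(np.squeeze(c)) for c in np.ravel(raw["channels"]))
    recordings = []
    for i in range(len(labels)):
        key = f"rec{i:04d}"
        if key not in raw:
            raise DatasetSchemaError(f"mat container missing variable {key!r}")
        recordings.append(
            EEGRecording(
                samples=np.asarray(raw[key], dtype=float),
                sampling_rate=float(fs[i]),
                label=EmotionClass.from_any(int(labels[i])),
                subject_id=int(subjects[i]),
                trial_id=int(trials[i]),
                channel_names=channels,
            )
        )
    return recordings


def _write_hdf5(recordings: list[EEGRecording], path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["channels"] = [c for c in recordings[0].channel_names]
        for rec in recordings:
            grp = f.require_group(f"subject_{rec.subject_id}")
            tg = grp.create_group(f"trial_{rec.trial_id}")
            tg.create_dataset("samples", data=rec.samples)
            tg.attrs["label"] = rec.label.name.lower()
            tg.attrs["fs"] = rec.sampling_rate
            tg.attrs["subject_id"] = rec.subject_id
            tg.attrs["trial_id"] = rec.trial_id


def _read_hdf5(path) -> list[EEGRecording]:
    import h5py

    recordings = []
    with h5py.File(path, "r") as f:
        channels = tuple(
            c.decode() if isinstance(c, bytes) else str(c)
            for c in f.attrs.get("channels", ())
        )
        for sname in sorted(f, key=lambda s: int(s.split("_")[1])):
            grp = f[sname]
            for tname in sorted(grp, key=lambda s: int(s.split("_")[1])):
                tg = grp[tname]
                if "samples" not in tg:
                    raise DatasetSchemaError(f"group /{sname}/{tname} missing 'samples'")
                if "label" not in tg.attrs:
                    raise DatasetSchemaError(f"group /{sname}/{tname} missing 'label' attr")
                try:
                    label = EmotionClass.from_any(tg.attrs["label"])
                except (KeyError, ValueError) as exc:
                    raise DatasetSchemaError(
                        f"group /{sname}/{tname} has unknown label "
                        f"{tg.attrs['label']!r}"
                    ) from exc
                recordings.append(
                    EEGRecording(
                        samples=np.asarray(tg["samples"], dtype=float),
                        sampling_rate=float(tg.attrs["fs"]),
                        label=label,
                        subject_id=int(tg.attrs["subject_id"]),
                        trial_id=int(tg.attrs["trial_id"]),
                        channel_names=channels,
                    )
                )
    # stable order: by subject then trial
    recordings.sort(key=lambda r: (r.subject_id, r.trial_id))
    return recordings
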