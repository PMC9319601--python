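"""End-to-end orchestration: data -> segments -> scalogram images ->
features -> entropy-based channel selection -> BoDF histograms ->
classical classifiers -> evaluation report.

Evaluation hygiene: every data-dependent fit — discretization bins,
channel ranking, the k-means vocabulary — happens inside each training
fold only; test-fold recordings never contribute vectors to the fold's
k-means.  The report records, per fold, exactly which recordings fed the
vocabulary so this can be audited.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .bodf import DEFAULT_K_GRID, build_vocabulary, encode_histogram, select_k
from .core import EEGRecording, EmotionClass
from .de_select import rank_channels
from .features import FeatureMatrix, extract_features, get_extractor
from .synth import SyntheticDatasetSpec, generate_dataset
from .timefreq import (
    WaveletSpec,
    cwt,
    default_scales,
    render_scalogram_image,
    segment_signal,
)

__all__ = [
    "ClassifierSpec",
    "PipelineConfig",
    "EvaluationReport",
    "default_classifiers",
    "make_classifier",
    "read_dataset",
    "recordings_to_features",
    "run_pipeline",
    "train_eval_classifiers",
    "permute_labels",
]

logger = logging.getLogger(__name__)


def read_dataset(path, format: str = "hdf5") -> list[EEGRecording]:
    """Read a dataset container (see :mod:`eegemo.io`)."""
    from . import io as _io

    return _io.read_dataset(path, format=format)


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

#: Supported (family, variant) pairs.  The variant names follow the
#: GUI-style labels common in the field's reports; the mapping to concrete
#: estimators is an interpretation layer: cubic SVM -> polynomial kernel of
#: degree 3; fine KNN -> 1 nearest neighbour; medium tree -> depth-capped
#: decision tree; subspace KNN -> random-subspace bagging of KNN learners.
_CLASSIFIER_MAP = {
    ("svm", "cubic"): "svm_cubic",
    ("knn", "fine"): "knn_fine",
    ("tree", "medium"): "tree_medium",
    ("ensemble", "subspace_knn"): "ensemble_subspace_knn",
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family/variant pair with optional hyperparameters."""

    family: str
    variant: str
    params: tuple = ()

    def __post_init__(self):
        if (self.family, self.variant) not in _CLASSIFIER_MAP:
            raise ValueError(
                f"unsupported classifier {self.family}/{self.variant}; "
                f"supported: {sorted(_CLASSIFIER_MAP)}"
            )

    @property
    def name(self) -> str:
        return _CLASSIFIER_MAP[(self.family, self.variant)]


def default_classifiers() -> list[ClassifierSpec]:
    """The four families used as classification heads: cubic SVM, fine
    KNN, medium tree, subspace-KNN ensemble."""
    return [
        ClassifierSpec("svm", "cubic"),
        ClassifierSpec("knn", "fine"),
        ClassifierSpec("tree", "medium"),
        ClassifierSpec("ensemble", "subspace_knn"),
    ]


def make_classifier(spec: ClassifierSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator for a spec (feature scaling
    included where the estimator is distance- or margin-based)."""
    from sklearn.ensemble import BaggingClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    params = dict(spec.params)
    rs = int(seed) % (2**31)
    if spec.name == "svm_cubic":
        return make_pipeline(
            StandardScaler(),
            SVC(kernel="poly", degree=3, coef0=1.0, C=params.get("C", 1.0)),
        )
    if spec.name == "knn_fine":
        return make_pipeline(
            StandardScaler(), KNeighborsClassifier(n_neighbors=params.get("n_neighbors", 1))
        )
    if spec.name == "tree_medium":
        return DecisionTreeClassifier(
            max_depth=params.get("max_depth", 20), random_state=rs
        )
    return make_pipeline(
        StandardScaler(),
        BaggingClassifier(
            estimator=KNeighborsClassifier(n_neighbors=params.get("n_neighbors", 1)),
            n_estimators=params.get("n_estimators", 30),
            max_features=0.5,
            bootstrap=False,
            random_state=rs,
        ),
    )


# ---------------------------------------------------------------------------
# Config and report
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything one end-to-end run depends on.

    ``dataset`` is either a :class:`~eegemo.synth.SyntheticDatasetSpec`
    (generated on the fly), a path string (with ``dataset_format``), or a
    ready list of recordings.
    """

    dataset: object = None
    dataset_format: str = "hdf5"
    window_len: int = 1000
    hop: int | None = None
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    n_scales: int = 64
    image_size: tuple[int, int] = (224, 224)
    colormap: str = "jet"
    extractor: str = "grid-stats"
    n_bins: int = 4
    n_features_per_channel: int = 20
    channel_budget: int | None = 26
    k: int | tuple = 8
    per_class_vocabulary: bool = True
    classifiers: list[ClassifierSpec] = field(default_factory=default_classifiers)
    folds: int = 5
    group_by_subject: bool = False
    seed: int = 0

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, (WaveletSpec, ClassifierSpec)):
                return asdict(o)
            if isinstance(o, SyntheticDatasetSpec):
                d = dict(o.__dict__)
                d["montage"] = {
                    "channel_names": d["montage"].channel_names,
                    "selected_subset": d["montage"].selected_subset,
                }
                d["class_band_gain"] = {int(k): v for k, v in d["class_band_gain"].items()}
                return d
            if isinstance(o, EEGRecording):
                return {
                    "subject": o.subject_id,
                    "trial": o.trial_id,
                    "label": int(o.label),
                    "sha": hashlib.sha256(o.samples.tobytes()).hexdigest()[:16],
                }
            if isinstance(o, np.integer):
                return int(o)
            if isinstance(o, np.floating):
                return float(o)
            raise TypeError(type(o))

        payload = json.dumps(self.__dict__, default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class EvaluationReport:
    """Cross-validated evaluation of one pipeline run."""

    accuracies: dict
    per_class: dict
    confusions: dict
    chosen_k: int
    selected_channels: list
    seed: int
    config_hash: str
    folds: int
    fold_train_recordings: list = field(default_factory=list)

    def __post_init__(self):
        for name, acc in self.accuracies.items():
            if not 0.0 <= acc <= 1.0:
                raise ValueError(f"accuracy for {name} outside [0, 1]")

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        return json.dumps(asdict(self), default=default, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# Feature stage
# ---------------------------------------------------------------------------


def recordings_to_features(
    recordings,
    wavelet: WaveletSpec | None = None,
    n_scales: int = 64,
    window_len: int = 1000,
    hop: int | None = None,
    image_size: tuple[int, int] = (224, 224),
    colormap: str = "jet",
    extractor_name: str = "grid-stats",
    channels=None,
) -> FeatureMatrix:
    """Segment recordings, render one scalogram image per (segment,
    channel) and extract features.

    ``channels`` restricts to a subset of electrode names (default: all).
    Rows are tagged with (recording, subject, trial, channel, label);
    ``recording`` enumerates segments in generation order.
    """
    recordings = list(recordings)
    if not recordings:
        raise ValueError("no recordings")
    wavelet = wavelet or WaveletSpec()
    extractor = get_extractor(extractor_name)
    fs = recordings[0].sampling_rate
    scales = default_scales(wavelet, fs, n_scales=n_scales)

    images, meta = [], []
    rec_counter = 0
    for rec in recordings:
        names = rec.channel_names or tuple(
            f"ch{i:02d}" for i in range(rec.n_channels)
        )
        use = [
            (i, nm)
            for i, nm in enumerate(names)
            if channels is None or nm in set(channels)
        ]
        if not use:
            raise ValueError("channel restriction removed every channel")
        for seg in segment_signal(rec, window_len=window_len, hop=hop):
            for i, nm in use:
                scal = cwt(seg.samples[i], wavelet, scales)
                images.append(
                    render_scalogram_image(
                        scal, size=image_size, colormap=colormap, scaling="log"
                    )
                )
                meta.append(
                    {
                        "recording": rec_counter,
                        "subject": rec.subject_id,
                        "trial": rec.trial_id,
                        "channel": nm,
                        "label": int(rec.label),
                    }
                )
            rec_counter += 1
    t0 = time.perf_counter()
    matrix = extract_features(images, extractor, meta)
    logger.info(
        json.dumps(
            {
                "stage": "extract",
                "rows": matrix.n_rows,
                "wall_s": round(time.perf_counter() - t0, 3),
            }
        )
    )
    return matrix


# ---------------------------------------------------------------------------
# Training / evaluation
# ---------------------------------------------------------------------------


def _recording_table(matrix: FeatureMatrix):
    meta = matrix.meta.drop_duplicates("recording")
    rec_ids = meta["recording"].to_numpy()
    labels = meta["label"].to_numpy()
    subjects = meta["subject"].to_numpy()
    return rec_ids, labels, subjects


def _split_folds(rec_ids, labels, subjects, folds, seed, group_by_subject):
    from sklearn.model_selection import StratifiedKFold, GroupKFold

    rs = int(seed) % (2**31)
    if group_by_subject:
        splitter = GroupKFold(n_splits=folds)
        return list(splitter.split(rec_ids, labels, groups=subjects))
    counts = np.bincount(labels)
    if np.min(counts[counts > 0]) < folds:
        raise ValueError(
            f"a class has fewer recordings ({np.min(counts[counts > 0])}) than folds ({folds})"
        )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
    return list(splitter.split(rec_ids, labels))


def run_pipeline(config: PipelineConfig) -> EvaluationReport:
    """Execute the full framework on a dataset and cross-validate the
    classification heads.  Deterministic given the master seed."""
    # --- stage: data ------------------------------------------------------
    ds = config.dataset
    if isinstance(ds, SyntheticDatasetSpec):
        recordings = generate_dataset(ds)
    elif isinstance(ds, (str,)) or hasattr(ds, "__fspath__"):
        recordings = read_dataset(ds, format=config.dataset_format)
    else:
        recordings = list(ds or [])
    if not recordings:
        raise RuntimeError("stage=data: empty dataset "
                           f"(config {config.config_hash()})")

    # --- stage: features (unsupervised, shared across folds) --------------
    matrix = recordings_to_features(
        recordings,
        wavelet=config.wavelet,
        n_scales=config.n_scales,
        window_len=config.window_len,
        hop=config.hop,
        image_size=config.image_size,
        colormap=config.colormap,
        extractor_name=config.extractor,
    )
    rec_ids, labels, subjects = _recording_table(matrix)
    n_channels = len(matrix.channels)
    budget = config.channel_budget or n_channels
    budget = min(budget, n_channels)

    splits = _split_folds(
        rec_ids, labels, subjects, config.folds, config.seed, config.group_by_subject
    )

    # k selection: fixed int, or a grid resolved per training fold
    k_grid = (config.k,) if isinstance(config.k, int) else tuple(config.k)

    specs = config.classifiers
    n_classes = int(labels.max()) + 1
    confusion = {s.name: np.zeros((n_classes, n_classes), int) for s in specs}
    fold_accs: dict[str, list[float]] = {s.name: [] for s in specs}
    fold_train_recordings = []
    chosen_ks = []

    for fold_no, (tr_idx, te_idx) in enumerate(splits):
        tr_recs = set(rec_ids[tr_idx])
        te_recs = set(rec_ids[te_idx])
        tr_mask = matrix.meta["recording"].isin(tr_recs).to_numpy()
        train_matrix = FeatureMatrix(
            matrix.values[tr_mask], matrix.meta.loc[tr_mask], list(matrix.feature_names)
        )
        # fold-local channel selection
        ranking = rank_channels(
            train_matrix,
            n_bins=config.n_bins,
            n_features_per_channel=config.n_features_per_channel,
        )
        selected = ranking.top(budget)
        train_sel = train_matrix.subset_channels(selected)

        # per-fold feature standardization: k-means distances are otherwise
        # dominated by the highest-variance feature columns
        mu = train_sel.values.mean(axis=0)
        sd = train_sel.values.std(axis=0)
        sd[sd == 0] = 1.0
        train_scaled = FeatureMatrix(
            (train_sel.values - mu) / sd, train_sel.meta, list(train_sel.feature_names)
        )

        if len(k_grid) == 1:
            k = k_grid[0]
        else:
            k = select_k(train_scaled, candidate_ks=k_grid, seed=config.seed)
        chosen_ks.append(k)

        vocab = build_vocabulary(
            train_scaled, k=k, per_class=config.per_class_vocabulary, seed=config.seed
        )
        fold_train_recordings.append(sorted(int(r) for r in tr_recs))

        def hists_for(recs):
            X, y = [], []
            for rec in sorted(recs):
                rows = np.flatnonzero(
                    (matrix.meta["recording"] == rec).to_numpy()
                    & matrix.meta["channel"].isin(selected).to_numpy()
                )
                h = encode_histogram(
                    (matrix.values[rows] - mu) / sd,
                    vocab,
                    recording_id=rec,
                    label=int(matrix.meta.loc[rows[0], "label"]),
                )
                X.append(h.counts)
                y.append(h.label)
            return np.vstack(X).astype(float), np.array(y)

        X_tr, y_tr = hists_for(tr_recs)
        X_te, y_te = hists_for(te_recs)

        for spec in specs:
            try:
                clf = make_classifier(spec, seed=config.seed)
                clf.fit(X_tr, y_tr)
                pred = clf.predict(X_te)
            except Exception as exc:
                raise RuntimeError(
                    f"stage=train/{spec.name} fold={fold_no} "
                    f"(config {config.config_hash()})"
                ) from exc
            fold_accs[spec.name].append(float(np.mean(pred == y_te)))
            for t, p in zip(y_te, pred):
                confusion[spec.name][t, p] += 1

    # full-data ranking, for reporting which channels the method favours
    full_ranking = rank_channels(
        matrix, n_bins=config.n_bins, n_features_per_channel=config.n_features_per_channel
    )
    selected_channels = full_ranking.top(budget)

    per_class = {}
    for name, cm in confusion.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            precision = np.where(cm.sum(0) > 0, np.diag(cm) / cm.sum(0), 0.0)
            recall = np.where(cm.sum(1) > 0, np.diag(cm) / cm.sum(1), 0.0)
        per_class[name] = {
            "precision": [round(float(v), 6) for v in precision],
            "recall": [round(float(v), 6) for v in recall],
        }

    return EvaluationReport(
        accuracies={n: round(float(np.mean(a)), 6) for n, a in fold_accs.items()},
        per_class=per_class,
        confusions={n: cm.tolist() for n, cm in confusion.items()},
        chosen_k=int(np.bincount(chosen_ks).argmax()),
        selected_channels=selected_channels,
        seed=int(config.seed),
        config_hash=config.config_hash(),
        folds=int(config.folds),
        fold_train_recordings=fold_train_recordings,
    )


def train_eval_classifiers(
    histograms,
    specs: list[ClassifierSpec] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold evaluation of classifier heads on precomputed
    BoDF histograms (list of :class:`~eegemo.bodf.HistogramFeature`)."""
    from sklearn.model_selection import StratifiedKFold

    specs = specs or default_classifiers()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.vstack([h.counts for h in histograms]).astype(float)
    y = np.array([h.label for h in histograms])
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if np.min(np.bincount(y)[classes]) < folds:
        raise ValueError("a class has fewer members than folds")
    n_classes = int(y.max()) + 1
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    confusion = {s.name: np.zeros((n_classes, n_classes), int) for s in specs}
    fold_accs: dict[str, list[float]] = {s.name: [] for s in specs}
    fold_train = []
    for tr, te in skf.split(X, y):
        fold_train.append(sorted(int(i) for i in tr))
        for spec in specs:
            clf = make_classifier(spec, seed=seed)
            clf.fit(X[tr], y[tr])
            pred = clf.predict(X[te])
            fold_accs[spec.name].append(float(np.mean(pred == y[te])))
            for t, p in zip(y[te], pred):
                confusion[spec.name][t, p] += 1
    per_class = {}
    for name, cm in confusion.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            precision = np.where(cm.sum(0) > 0, np.diag(cm) / cm.sum(0), 0.0)
            recall = np.where(cm.sum(1) > 0, np.diag(cm) / cm.sum(1), 0.0)
        per_class[name] = {
            "precision": [round(float(v), 6) for v in precision],
            "recall": [round(float(v), 6) for v in recall],
        }
    return EvaluationReport(
        accuracies={n: round(float(np.mean(a)), 6) for n, a in fold_accs.items()},
        per_class=per_class,
        confusions={n: cm.tolist() for n, cm in confusion.items()},
        chosen_k=0,
        selected_channels=[],
        seed=int(seed),
        config_hash="histograms",
        folds=int(folds),
        fold_train_recordings=fold_train,
    )


def permute_labels(recordings, seed: int = 0) -> list[EEGRecording]:
    """Return copies of the recordings with labels randomly permuted
    across the dataset — the chance-level control for any claimed
    class separation."""
    recordings = list(recordings)
    rng = np.random.default_rng(int(seed))
    labels = [r.label for r in recordings]
    perm = rng.permutation(len(labels))
    out = []
    for rec, j in zip(recordings, perm):
        out.append(
            EEGRecording(
                samples=rec.samples.copy(),
                sampling_rate=rec.sampling_rate,
                label=EmotionClass.from_any(labels[j]),
                subject_id=rec.subject_id,
                trial_id=rec.trial_id,
                channel_names=rec.channel_names,
            )
        )
    return out
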