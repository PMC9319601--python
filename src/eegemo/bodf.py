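"""Bag-of-Deep-Features (BoDF) encoding.

Selected per-channel feature vectors are clustered with k-means into a
*vocabulary* of centroids — by default one codebook per emotion class,
concatenated in class order — and every recording is re-expressed as the
histogram of its vectors' Euclidean-nearest vocabulary entries.  The
histogram length ``n_classes * k`` (e.g. 3 x 14 = 42) is far below the
raw feature width, which is the point: a compact, classifier-friendly
summary of where a recording's channel features live in feature space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix

__all__ = [
    "DEFAULT_K_GRID",
    "Vocabulary",
    "HistogramFeature",
    "build_vocabulary",
    "encode_histogram",
    "encode_matrix",
    "select_k",
    "silhouette_evaluator",
]

logger = logging.getLogger(__name__)

#: The default cluster-count grid explored during vocabulary sizing.
DEFAULT_K_GRID: tuple[int, ...] = (8, 10, 12, 14)


@dataclass
class Vocabulary:
    """k-means codebook: ``centroids`` maps class label (or ``None`` when
    pooled) to a (k, q) centroid matrix; ``codebook`` concatenates them in
    ascending class order."""

    centroids: dict
    k: int
    seed: int
    inertia: dict = field(default_factory=dict)

    def __post_init__(self):
        for key, c in self.centroids.items():
            c = np.asarray(c, dtype=float)
            if c.ndim != 2 or not np.all(np.isfinite(c)):
                raise ValueError(f"centroids for {key!r} must be a finite 2-D array")
            self.centroids[key] = c
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def classes(self) -> list:
        return sorted(self.centroids, key=lambda c: -1 if c is None else int(c))

    @property
    def codebook(self) -> np.ndarray:
        return np.vstack([self.centroids[c] for c in self.classes])

    @property
    def size(self) -> int:
        return sum(len(c) for c in self.centroids.values())


@dataclass
class HistogramFeature:
    """Nearest-vocabulary count vector for one recording."""

    counts: np.ndarray
    recording_id: int
    label: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative 1-D vector")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")


def _fit_kmeans(vectors: np.ndarray, k: int, seed: int):
    from sklearn.cluster import KMeans

    km = KMeans(
        n_clusters=k,
        n_init=10,
        init="k-means++",
        algorithm="lloyd",
        random_state=int(seed) % (2**31),
    )
    km.fit(vectors)
    return km.cluster_centers_, float(km.inertia_)


def build_vocabulary(
    matrix: FeatureMatrix | np.ndarray,
    k: int,
    per_class: bool = True,
    seed: int = 0,
    labels=None,
) -> Vocabulary:
    """Cluster feature vectors into a vocabulary.

    With ``per_class=True`` (default) one k-means codebook is fitted per
    emotion class and concatenated; ``per_class=False`` pools all vectors
    into a single codebook.  Deterministic given ``seed``; k-means++ with
    10 restarts keeps the best-inertia solution.
    """
    if isinstance(matrix, FeatureMatrix):
        vectors = matrix.values
        labels = matrix.meta["label"].to_numpy()
    else:
        vectors = np.asarray(matrix, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] == 0:
        raise ValueError("need a non-empty 2-D array of vectors")
    centroids: dict = {}
    inertia: dict = {}
    if per_class:
        if labels is None:
            raise ValueError("per-class vocabulary requires labels")
        labels = np.asarray(labels)
        for cls in np.unique(labels):
            sub = vectors[labels == cls]
            if sub.shape[0] == 0:
                raise ValueError(f"class {cls!r} has no vectors")
            if k > sub.shape[0]:
                raise ValueError(
                    f"k={k} exceeds the {sub.shape[0]} vectors of class {cls!r}"
                )
            centroids[int(cls)], inertia[int(cls)] = _fit_kmeans(sub, k, seed)
    else:
        if k > vectors.shape[0]:
            raise ValueError(f"k={k} exceeds the {vectors.shape[0]} vectors")
        centroids[None], inertia[None] = _fit_kmeans(vectors, k, seed)
    return Vocabulary(centroids, k=k, seed=int(seed), inertia=inertia)


def encode_histogram(
    vectors: np.ndarray,
    vocabulary: Vocabulary,
    recording_id: int = 0,
    label: int = 0,
) -> HistogramFeature:
    """Count each vector into the bin of its Euclidean-nearest codebook
    entry (ties to the lowest centroid index).  Counts always sum to the
    number of encoded vectors."""
    from scipy.spatial.distance import cdist

    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    codebook = vocabulary.codebook
    if vectors.shape[1] != codebook.shape[1]:
        raise ValueError(
            f"vector length {vectors.shape[1]} != centroid length {codebook.shape[1]}"
        )
    nearest = np.argmin(cdist(vectors, codebook), axis=1)  # argmin takes lowest index on ties
    counts = np.bincount(nearest, minlength=len(codebook)).astype(np.int64)
    return HistogramFeature(counts, recording_id=int(recording_id), label=int(label))


def encode_matrix(matrix: FeatureMatrix, vocabulary: Vocabulary) -> list[HistogramFeature]:
    """Encode every recording of a feature matrix: each recording's
    (channel, feature) rows become one histogram."""
    out = []
    for rec in dict.fromkeys(matrix.meta["recording"]):
        rows = np.flatnonzero((matrix.meta["recording"] == rec).to_numpy())
        label = int(matrix.meta.loc[rows[0], "label"])
        out.append(
            encode_histogram(matrix.values[rows], vocabulary, recording_id=rec, label=label)
        )
    return out


def silhouette_evaluator(vectors: np.ndarray, labels=None):
    """Evaluator scoring a candidate k by the mean silhouette of a pooled
    k-means clustering — useful when the latent cluster count, not the
    downstream accuracy, is the quantity of interest."""
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    vectors = np.asarray(vectors, dtype=float)

    def evaluate(k: int, seed: int) -> float:
        km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31))
        assignment = km.fit_predict(vectors)
        return float(silhouette_score(vectors, assignment))

    return evaluate


def accuracy_evaluator(matrix: FeatureMatrix, folds: int = 3):
    """Default evaluator: stratified cross-validated accuracy of a
    cubic-kernel SVM on the BoDF histograms built with the candidate k."""

    def evaluate(k: int, seed: int) -> float:
        from sklearn.model_selection import StratifiedKFold
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        vocab = build_vocabulary(matrix, k=k, per_class=True, seed=seed)
        hists = encode_matrix(matrix, vocab)
        X = np.vstack([h.counts for h in hists]).astype(float)
        y = np.array([h.label for h in hists])
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
        accs = []
        for tr, te in skf.split(X, y):
            clf = make_pipeline(StandardScaler(), SVC(kernel="poly", degree=3, coef0=1.0))
            clf.fit(X[tr], y[tr])
            accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
        return float(np.mean(accs))

    return evaluate


def select_k(
    matrix,
    candidate_ks=DEFAULT_K_GRID,
    evaluator=None,
    seed: int = 0,
) -> int:
    """Pick the best cluster count from a candidate grid.

    ``evaluator(k, seed) -> score`` is maximized; ties (and constant
    evaluators) resolve to the lowest k.  A single candidate is returned
    without evaluation.  The full score table is logged.
    """
    ks = sorted(int(k) for k in candidate_ks)
    if not ks:
        raise ValueError("need at least one candidate k")
    if len(ks) == 1:
        return ks[0]
    if evaluator is None:
        if not isinstance(matrix, FeatureMatrix):
            raise ValueError("default evaluator requires a FeatureMatrix")
        evaluator = accuracy_evaluator(matrix)
    scores = {}
    for k in ks:
        try:
            scores[k] = float(evaluator(k, seed))
        except Exception as exc:
            raise RuntimeError(f"evaluator failed at k={k}") from exc
    logger.info("select_k scores: %s", scores)
    return max(ks, key=lambda k: (scores[k], -k))
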