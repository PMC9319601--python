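"""Rough-set differential-entropy feature and channel selection.

Features are discretized into a *decision table* ``(U, C ∪ {D})``: the
universe ``U`` of objects (recordings), discrete condition attributes
``C`` (feature columns), and the decision attribute ``D`` (the emotion
label, carried for downstream stratification only — it does not enter the
entropy itself).

Every attribute subset ``P ⊆ C`` induces an *indiscernibility partition*
``U/P``: objects fall in the same block iff they agree on every attribute
of ``P``.  The differential entropy of ``P`` with respect to ``C`` is

.. math:: E(P \\mid U \\oplus C) = -\\frac{1}{|U|} \\sum_{x \\in U}
          \\log_2 \\frac{|[x]_C \\cap [x]_P|}{|[x]_P|}
        = -\\frac{1}{|U|} \\sum_{x \\in U}
          \\log_2 \\frac{|[x]_C|}{|[x]_P|},

the simplification holding because ``[x]_C ⊆ [x]_P`` whenever ``P ⊆ C``.
``E = 0`` iff ``U/P = U/C`` (the subset carries the full set's
discriminating knowledge); the value grows as ``P``'s partition coarsens,
up to ``log2 |U|``.

Channel ranking (DECS)
----------------------
Each channel is scored by the entropy of its own feature block against
the condition set pooled over all channels.  When the full set ``C``
shatters the universe (typical for many-dimensional continuous features),
the score reduces to the mean log-size of the channel's partition blocks:
channels whose features are mutually redundant — i.e. driven by a common
underlying process such as class-dependent band power — produce coarse
partitions and *high* entropy, while channels of independent noise
shatter the universe and score near zero.  Channels are therefore ranked
by descending entropy ("high-information" first), with ties broken by
ascending channel index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix

__all__ = [
    "DecisionTable",
    "Partition",
    "DEScore",
    "ChannelRanking",
    "discretize_features",
    "discretize_columns",
    "partition_by",
    "de_subset_entropy",
    "de_subset_entropy_bruteforce",
    "rank_channels",
    "select_features",
]


# ---------------------------------------------------------------------------
# Decision tables and partitions
# ---------------------------------------------------------------------------


@dataclass
class DecisionTable:
    """Discrete-valued decision table ``(U, C ∪ {D})``.

    ``data`` holds one row per object; ``condition_attributes`` name the
    discrete condition columns and ``decision_attribute`` the label
    column.  The decision attribute never overlaps the condition set.
    """

    data: pd.DataFrame
    condition_attributes: list[str]
    decision_attribute: str = "label"

    def __post_init__(self):
        self.condition_attributes = list(self.condition_attributes)
        missing = [
            c
            for c in self.condition_attributes + [self.decision_attribute]
            if c not in self.data.columns
        ]
        if missing:
            raise ValueError(f"columns missing from table: {missing}")
        if self.decision_attribute in self.condition_attributes:
            raise ValueError("decision attribute must not be a condition attribute")
        if self.data.isna().any().any():
            raise ValueError("decision table must not contain missing values")
        self.data = self.data.reset_index(drop=True)

    @property
    def universe_size(self) -> int:
        return len(self.data)

    def to_tsv(self, path) -> None:
        """Export as TSV: condition attributes first, decision last."""
        cols = self.condition_attributes + [self.decision_attribute]
        self.data[cols].to_csv(path, sep="\t", index=False)


@dataclass
class Partition:
    """Indiscernibility partition of the universe: disjoint blocks of
    positional object indices covering U exactly."""

    blocks: list[np.ndarray]
    universe_size: int

    def __post_init__(self):
        total = sum(len(b) for b in self.blocks)
        seen = np.concatenate([np.asarray(b) for b in self.blocks]) if self.blocks else np.array([], int)
        if total != self.universe_size or len(np.unique(seen)) != total:
            raise ValueError("blocks must partition the universe exactly")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_sizes(self) -> np.ndarray:
        return np.array(sorted(len(b) for b in self.blocks))


@dataclass(frozen=True)
class DEScore:
    """Entropy value (bits) of an attribute subset P relative to C."""

    subset: tuple[str, ...]
    value: float


@dataclass
class ChannelRanking:
    """Per-channel differential-entropy scores plus the selection order."""

    channels: list[str]
    scores: list[DEScore]
    order: list[int]  # channel indices, best first
    degenerate: bool = False

    def top(self, budget: int) -> list[str]:
        """Names of the ``budget`` best channels, in montage order."""
        if budget < 1:
            raise ValueError("budget must be >= 1")
        if budget > len(self.channels):
            raise ValueError(
                f"budget {budget} exceeds available channels ({len(self.channels)})"
            )
        chosen = sorted(self.order[:budget])
        return [self.channels[i] for i in chosen]


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


def discretize_columns(
    values: np.ndarray, n_bins: int = 10, method: str = "equal_frequency"
) -> np.ndarray:
    """Discretize each column of a float matrix to integer codes
    ``0..n_bins-1``; constant columns collapse to a single code (warning).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if method not in ("equal_frequency", "equal_width"):
        raise ValueError("method must be 'equal_frequency' or 'equal_width'")
    values = np.asarray(values, dtype=float)
    codes = np.empty(values.shape, dtype=np.int64)
    n_constant = 0
    for j in range(values.shape[1]):
        col = values[:, j]
        if np.ptp(col) == 0:
            codes[:, j] = 0
            n_constant += 1
            continue
        if method == "equal_frequency":
            binned = pd.qcut(col, q=n_bins, labels=False, duplicates="drop")
            codes[:, j] = np.asarray(binned, dtype=np.int64)
        else:
            binned = pd.cut(col, bins=n_bins, labels=False, include_lowest=True)
            codes[:, j] = np.asarray(binned, dtype=np.int64)
    if n_constant:
        warnings.warn(
            f"{n_constant} constant feature column(s) collapsed to one bin",
            stacklevel=2,
        )
    return codes


def discretize_features(
    matrix: FeatureMatrix, n_bins: int = 10, method: str = "equal_frequency"
) -> DecisionTable:
    """Build a decision table from a feature matrix.

    Each feature column becomes a condition attribute with integer codes;
    the emotion label becomes the decision attribute.
    """
    codes = discretize_columns(matrix.values, n_bins=n_bins, method=method)
    df = pd.DataFrame(codes, columns=matrix.feature_names)
    df["label"] = matrix.meta["label"].to_numpy()
    return DecisionTable(df, list(matrix.feature_names), "label")


# ---------------------------------------------------------------------------
# Partitions and entropy
# ---------------------------------------------------------------------------


def _check_attrs(table: DecisionTable, attrs) -> list[str]:
    attrs = list(attrs)
    allowed = set(table.condition_attributes) | {table.decision_attribute}
    unknown = [a for a in attrs if a not in allowed]
    if unknown:
        raise KeyError(f"unknown attributes: {unknown}")
    return attrs


def partition_by(table: DecisionTable, attrs) -> Partition:
    """Indiscernibility partition ``U/attrs``.

    An empty attribute set yields the single-block (trivial) partition.
    Refining the attribute set refines the partition.
    """
    attrs = _check_attrs(table, attrs)
    n = table.universe_size
    if not attrs:
        return Partition([np.arange(n)], n)
    groups = table.data.groupby(attrs, sort=False).indices
    blocks = [np.sort(np.asarray(idx)) for idx in groups.values()]
    blocks.sort(key=lambda b: int(b[0]))
    return Partition(blocks, n)


def _group_sizes(table: DecisionTable, attrs: list[str]) -> np.ndarray:
    """|[x]_attrs| for every object x, as an aligned vector."""
    n = table.universe_size
    if not attrs:
        return np.full(n, n, dtype=np.int64)
    return (
        table.data.groupby(attrs, sort=False)[table.decision_attribute]
        .transform("size")
        .to_numpy(dtype=np.int64)
    )


def de_subset_entropy(table: DecisionTable, subset) -> DEScore:
    """Differential entropy ``E(P | U ⊕ C)`` in bits (fast path).

    Uses the simplified form ``-(1/|U|) Σ log2(|[x]_C| / |[x]_P|)``,
    valid because ``[x]_C ⊆ [x]_P`` for ``P ⊆ C``.  Zero iff
    ``U/P = U/C``; at most ``log2 |U|``.
    """
    subset = list(subset)
    bad = [a for a in subset if a not in table.condition_attributes]
    if bad:
        raise KeyError(f"subset attributes not in C: {bad}")
    if table.universe_size == 0:
        raise ValueError("empty universe")
    size_c = _group_sizes(table, table.condition_attributes)
    size_p = _group_sizes(table, subset)
    value = float(-np.mean(np.log2(size_c / size_p)))
    # exact zero when the partitions coincide, avoiding -0.0 noise
    if np.array_equal(size_c, size_p):
        value = 0.0
    return DEScore(tuple(subset), value)


def de_subset_entropy_bruteforce(table: DecisionTable, subset) -> DEScore:
    """Oracle twin of :func:`de_subset_entropy`: a direct double loop over
    the universe with explicit indiscernibility-class intersections,
    following the unsimplified definition term by term.

    Intended for small tables (|U| <= 512); used to cross-validate the
    fast path.
    """
    subset = list(subset)
    bad = [a for a in subset if a not in table.condition_attributes]
    if bad:
        raise KeyError(f"subset attributes not in C: {bad}")
    n = table.universe_size
    if n == 0:
        raise ValueError("empty universe")
    if n > 512:
        raise ValueError("brute-force oracle limited to |U| <= 512")
    c_cols = [table.data[a].to_numpy() for a in table.condition_attributes]
    p_cols = [table.data[a].to_numpy() for a in subset]

    def eq_class(cols, x):
        if not cols:
            return set(range(n))
        mask = np.ones(n, dtype=bool)
        for col in cols:
            mask &= col == col[x]
        return set(np.flatnonzero(mask))

    total = 0.0
    for x in range(n):
        xc = eq_class(c_cols, x)
        xp = eq_class(p_cols, x)
        total += np.log2(len(xc & xp) / len(xp))
    value = float(-total / n)
    return DEScore(tuple(subset), 0.0 if value == 0 else value)


# ---------------------------------------------------------------------------
# Channel ranking and selection
# ---------------------------------------------------------------------------


def _representative_columns(block: np.ndarray, m: int) -> np.ndarray:
    """Indices of the ``m`` most representative columns of a channel's
    feature block: highest mean absolute correlation with the block's
    other columns.  Label-free; constant columns are excluded."""
    sd = block.std(axis=0)
    live = np.flatnonzero(sd > 0)
    if live.size == 0:
        return live
    if live.size <= m:
        return live
    z = (block[:, live] - block[:, live].mean(0)) / sd[live]
    corr = np.abs(z.T @ z) / block.shape[0]
    np.fill_diagonal(corr, 0.0)
    score = corr.mean(axis=1)
    top = np.argsort(-score, kind="stable")[:m]
    return live[np.sort(top)]


def rank_channels(
    matrix: FeatureMatrix,
    montage=None,
    n_bins: int = 4,
    n_features_per_channel: int = 20,
) -> ChannelRanking:
    """Differential-entropy channel ranking (DECS).

    For each channel the feature matrix rows tagged with that channel are
    assembled into a per-recording block; the ``n_features_per_channel``
    most representative (mutually correlated, label-free) columns are
    discretized by equal-frequency binning and scored as the subset ``P``
    against the condition set ``C`` pooled over all channels.  Channels
    are ordered by descending entropy, ties by ascending channel index.

    A single-channel matrix yields a degenerate ranking (returned with
    ``degenerate=True``).
    """
    if "channel" not in matrix.meta.columns:
        raise ValueError("feature matrix rows must be tagged with channel ids")
    channels = matrix.channels
    if montage is not None:
        known = [c for c in montage.channel_names if c in set(channels)]
        if known:
            channels = known
    # pivot: one row per recording, columns grouped by channel
    rec_ids = list(dict.fromkeys(matrix.meta["recording"]))
    rec_pos = {r: i for i, r in enumerate(rec_ids)}
    n_rec = len(rec_ids)

    blocks: dict[str, np.ndarray] = {}
    for ch in channels:
        rows = matrix.rows_for_channel(ch)
        block = np.zeros((n_rec, matrix.n_features))
        recs = matrix.meta.loc[rows, "recording"].to_numpy()
        if len(set(recs)) != n_rec:
            raise ValueError(f"channel {ch!r} missing rows for some recordings")
        for r, row in zip(recs, rows):
            block[rec_pos[r]] = matrix.values[row]
        blocks[ch] = block

    # representative columns per channel, shared discretization settings
    code_cols: list[np.ndarray] = []
    col_names: list[str] = []
    per_channel_attrs: dict[str, list[str]] = {}
    for ch in channels:
        block = blocks[ch]
        keep = _representative_columns(block, n_features_per_channel)
        codes = discretize_columns(
            block[:, keep] if keep.size else np.zeros((n_rec, 0)),
            n_bins=n_bins,
        ) if keep.size else np.zeros((n_rec, 0), dtype=np.int64)
        names = [f"{ch}__{matrix.feature_names[k]}" for k in keep]
        per_channel_attrs[ch] = names
        col_names.extend(names)
        code_cols.append(codes)

    codes_all = np.hstack(code_cols) if code_cols else np.zeros((n_rec, 0), int)
    df = pd.DataFrame(codes_all, columns=col_names)
    labels = (
        matrix.meta.drop_duplicates("recording").set_index("recording")["label"]
    )
    df["label"] = [labels[r] for r in rec_ids]
    table = DecisionTable(df, col_names, "label")

    # |[x]_C| computed once; per-pair |[x]_P| by joint coding.  This is
    # the same quantity de_subset_entropy computes (tested against it),
    # evaluated without re-grouping the full condition set per pair.
    size_c = _group_sizes(table, col_names)
    col_offset = {}
    pos = 0
    for ch in channels:
        col_offset[ch] = pos
        pos += len(per_channel_attrs[ch])

    scores = []
    for ch in channels:
        attrs = per_channel_attrs[ch]
        if len(attrs) < 2:
            scores.append(DEScore((ch,), 0.0))
            continue
        # Mean subset entropy over feature pairs.  Pairs are the smallest
        # subsets whose partitions expose inter-feature redundancy; the
        # mean over all pairs is a far lower-variance channel statistic
        # than one exact joint match across every representative feature.
        base = col_offset[ch]
        cols = codes_all[:, base : base + len(attrs)]
        vals = []
        for i in range(cols.shape[1]):
            for j in range(i + 1, cols.shape[1]):
                joint = cols[:, i] * (cols[:, j].max() + 1) + cols[:, j]
                _, inv, cnt = np.unique(joint, return_inverse=True, return_counts=True)
                size_p = cnt[inv]
                vals.append(float(-np.mean(np.log2(size_c / size_p))))
        scores.append(DEScore((ch,), float(np.mean(vals))))
    order = sorted(
        range(len(channels)), key=lambda i: (-scores[i].value, i)
    )
    return ChannelRanking(
        channels=list(channels),
        scores=scores,
        order=order,
        degenerate=len(channels) < 2,
    )


def select_features(
    matrix: FeatureMatrix, ranking: ChannelRanking, budget: int
) -> FeatureMatrix:
    """Keep the rows of the top-``budget`` channels, original order
    preserved.  ``budget`` equal to the channel count is the identity."""
    keep = ranking.top(budget)
    return matrix.subset_channels(keep)
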