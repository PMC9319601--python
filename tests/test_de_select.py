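"""Rough-set differential entropy: worked examples, oracle equivalence,
range/monotonicity properties, and channel ranking behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eegemo.de_select import (
    DecisionTable,
    de_subset_entropy,
    de_subset_entropy_bruteforce,
    discretize_features,
    partition_by,
    rank_channels,
    select_features,
)

from conftest import toy_feature_matrix


def table_from(rows, attrs=None, labels=None) -> DecisionTable:
    rows = np.atleast_2d(rows)
    attrs = attrs or [f"a{i}" for i in range(rows.shape[1])]
    df = pd.DataFrame(rows, columns=attrs)
    df["label"] = labels if labels is not None else 0
    return DecisionTable(df, attrs, "label")


random_tables = st.integers(0, 10_000).map(
    lambda seed: _random_table(np.random.default_rng(seed))
)


def _random_table(rng) -> DecisionTable:
    n = int(rng.integers(2, 9))
    n_attr = int(rng.integers(1, 5))
    rows = rng.integers(0, 3, size=(n, n_attr))
    return table_from(rows, labels=rng.integers(0, 3, size=n))


class TestDiscretize:
    def test_constant_column_collapses_with_warning(self):
        m = toy_feature_matrix(np.ones((6, 3)), ["c0"], [0, 1, 2, 0, 1, 2])
        with pytest.warns(UserWarning):
            t = discretize_features(m, n_bins=4)
        assert (t.data[t.condition_attributes] == 0).all().all()

    def test_bijective_when_bins_match_distinct_values(self):
        vals = np.array([[3.0], [1.0], [2.0], [0.0]])
        m = toy_feature_matrix(vals, ["c0"], [0, 1, 2, 0])
        t = discretize_features(m, n_bins=4)
        codes = t.data[t.condition_attributes[0]].to_numpy()
        assert sorted(codes) == [0, 1, 2, 3]
        assert np.all(np.argsort(codes) == np.argsort(vals.ravel()))

    def test_equal_frequency_bins_balanced(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(200, 1))
        m = toy_feature_matrix(vals, ["c0"], rng.integers(0, 3, 200))
        t = discretize_features(m, n_bins=4)
        occ = t.data[t.condition_attributes[0]].value_counts()
        assert occ.max() - occ.min() <= 1

    def test_bad_parameters(self):
        m = toy_feature_matrix(np.ones((4, 2)), ["c0"], [0, 1, 0, 1])
        with pytest.raises(ValueError):
            discretize_features(m, n_bins=1)
        with pytest.raises(ValueError):
            discretize_features(m, method="magic")


class TestPartition:
    def test_empty_attrs_single_block(self):
        t = table_from([[0], [1], [0]])
        p = partition_by(t, [])
        assert p.n_blocks == 1 and len(p.blocks[0]) == 3

    def test_all_distinct_rows_all_singletons(self):
        t = table_from([[0, 0], [0, 1], [1, 0], [1, 1]])
        p = partition_by(t, ["a0", "a1"])
        assert p.n_blocks == 4

    def test_binary_attribute_blocks(self):
        t = table_from([[0], [0], [1], [1]])
        p = partition_by(t, ["a0"])
        blocks = sorted(tuple(b) for b in p.blocks)
        assert blocks == [(0, 1), (2, 3)]

    def test_unknown_attribute_rejected(self):
        with pytest.raises(KeyError):
            partition_by(table_from([[0]]), ["nope"])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(random_tables)
    def test_adding_attributes_refines(self, t):
        sub = t.condition_attributes[:1]
        p_coarse = partition_by(t, sub)
        p_fine = partition_by(t, t.condition_attributes)
        fine_sets = [set(b) for b in p_fine.blocks]
        for b in p_coarse.blocks:
            bs = set(b)
            assert all(f <= bs or not (f & bs) for f in fine_sets)


class TestSubsetEntropy:
    def test_full_set_scores_exact_zero(self):
        t = table_from([[0, 1], [1, 0], [1, 1], [0, 0]])
        assert de_subset_entropy(t, t.condition_attributes).value == 0.0

    def test_worked_four_object_example(self):
        # C-partition {x1},{x2},{x3,x4}; P-partition {x1,x2},{x3,x4}:
        # contributions (-1, -1, 0, 0) so E = 0.5 bits
        t = table_from([[0, 0], [0, 1], [1, 0], [1, 0]])
        assert de_subset_entropy(t, ["a0"]).value == pytest.approx(0.5, abs=1e-12)

    def test_singletons_vs_trivial_partition_closed_form(self):
        # C shatters 4 objects, P is one block: E = log2(4) = 2 bits
        t = table_from([[0, 0], [1, 0], [2, 0], [3, 0]])
        assert de_subset_entropy(t, ["a1"]).value == pytest.approx(2.0, abs=1e-12)

    def test_empty_universe_rejected(self):
        df = pd.DataFrame({"a0": [], "label": []})
        t = DecisionTable(df, ["a0"], "label")
        with pytest.raises(ValueError):
            de_subset_entropy(t, ["a0"])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(random_tables, st.integers(0, 100))
    def test_fast_path_equals_bruteforce(self, t, pick):
        k = pick % (len(t.condition_attributes) + 1)
        subset = t.condition_attributes[:k]
        fast = de_subset_entropy(t, subset).value
        brute = de_subset_entropy_bruteforce(t, subset).value
        assert abs(fast - brute) <= 1e-12

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(random_tables)
    def test_range_and_monotonicity(self, t):
        n = t.universe_size
        attrs = t.condition_attributes
        prev = None
        # growing subsets refine the partition, so E must not increase
        for k in range(len(attrs) + 1):
            e = de_subset_entropy(t, attrs[:k]).value
            assert 0.0 <= e <= np.log2(n) + 1e-12
            if prev is not None:
                assert e <= prev + 1e-12
            prev = e


class TestChannelRanking:
    def _matrix(self, blocks, labels):
        """blocks: dict channel -> (n_rec, q) values."""
        channels = list(blocks)
        n_rec = next(iter(blocks.values())).shape[0]
        rows = np.vstack(
            [blocks[ch][r] for r in range(n_rec) for ch in channels]
        )
        return toy_feature_matrix(rows, channels, labels)

    def test_identical_channels_tie_break_by_index(self):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(12, 30))
        m = self._matrix({"c1": block, "c0": block, "c2": block}, rng.integers(0, 3, 12))
        r = rank_channels(m, n_bins=2, n_features_per_channel=4)
        assert len({s.value for s in r.scores}) == 1
        assert r.order == [0, 1, 2]

    def test_single_channel_degenerate(self):
        rng = np.random.default_rng(1)
        m = self._matrix({"only": rng.normal(size=(8, 10))}, rng.integers(0, 2, 8))
        r = rank_channels(m)
        assert r.degenerate and r.top(1) == ["only"]

    def test_pairwise_score_matches_public_entropy(self):
        # channel with exactly two representative features: the ranking
        # score must equal the subset entropy of that single pair,
        # computed through the public (oracle-validated) route
        rng = np.random.default_rng(2)
        latent = rng.normal(size=16)
        block = np.column_stack([latent + 0.1 * rng.normal(size=16),
                                 latent + 0.1 * rng.normal(size=16)])
        noise = rng.normal(size=(16, 2))
        m = self._matrix({"sig": block, "noi": noise}, rng.integers(0, 3, 16))
        r = rank_channels(m, n_bins=3, n_features_per_channel=2)
        from eegemo.de_select import discretize_columns

        codes_sig = discretize_columns(block, n_bins=3)
        codes_noi = discretize_columns(noise, n_bins=3)
        df = pd.DataFrame(
            np.hstack([codes_sig, codes_noi]), columns=["s0", "s1", "n0", "n1"]
        )
        df["label"] = 0
        t = DecisionTable(df, ["s0", "s1", "n0", "n1"], "label")
        expected = de_subset_entropy(t, ["s0", "s1"]).value
        got = {s.subset[0]: s.value for s in r.scores}["sig"]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_correlated_channel_outranks_noise(self):
        rng = np.random.default_rng(3)
        latent = np.repeat(rng.normal(size=4), 5)  # 4 latent groups of 5
        sig = latent[:, None] + 0.05 * rng.normal(size=(20, 12))
        noi = rng.normal(size=(20, 12))
        m = self._matrix({"noi": noi, "sig": sig}, rng.integers(0, 3, 20))
        r = rank_channels(m, n_bins=4, n_features_per_channel=6)
        assert r.top(1) == ["sig"]

    def test_select_features_budget(self):
        rng = np.random.default_rng(4)
        blocks = {f"c{i}": rng.normal(size=(10, 8)) for i in range(4)}
        m = self._matrix(blocks, rng.integers(0, 3, 10))
        r = rank_channels(m, n_features_per_channel=4)
        full = select_features(m, r, budget=4)
        np.testing.assert_array_equal(full.values, m.values)
        sub = select_features(m, r, budget=2)
        assert len(sub.channels) == 2
        with pytest.raises(ValueError):
            select_features(m, r, budget=9)

    def test_export_tsv_layout(self, tmp_path):
        t = table_from([[0, 1], [1, 0]], labels=[1, 2])
        path = tmp_path / "table.tsv"
        t.to_tsv(path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["a0", "a1", "label"]
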