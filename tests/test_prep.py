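"""Descriptor cleaning, intercorrelation filtering, normalization,
feature selection and Kennard-Stone splitting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from docksel.prep import (Normalizer, clean_descriptors,
                          filter_intercorrelated, gfa_select,
                          kennard_stone_split, rfe_select, split_diagnostics)


def _desc_table(mat, names=None):
    names = names or [f"d{j}" for j in range(mat.shape[1])]
    df = pd.DataFrame(mat, columns=names)
    df.insert(0, "ligand_id", [f"L{i}" for i in range(len(df))])
    return df


class TestCleanDescriptors:
    def test_missing_and_constant_columns_dropped(self, rng):
        mat = rng.normal(size=(10, 3))
        table = _desc_table(mat)
        table["with_gap"] = rng.normal(size=10)
        table.loc[3, "with_gap"] = np.nan
        table["flat"] = 7.0
        out = clean_descriptors(table)
        assert set(out.columns) == {"ligand_id", "d0", "d1", "d2"}

    def test_informative_table_unchanged(self, rng):
        table = _desc_table(rng.normal(size=(8, 4)))
        out = clean_descriptors(table)
        pd.testing.assert_frame_equal(out, table)

    def test_everything_removed_is_an_error(self):
        table = _desc_table(np.ones((5, 2)))
        with pytest.raises(ValueError, match="every descriptor"):
            clean_descriptors(table)


class TestIntercorrelationFilter:
    def test_perfectly_correlated_pair_resolved(self, rng):
        x = rng.normal(size=30)
        table = _desc_table(np.column_stack([x, 2 * x, rng.normal(size=30)]),
                            ["c1", "c2", "c3"])
        out = filter_intercorrelated(table)
        kept = set(out.columns) - {"ligand_id"}
        assert "c3" in kept
        assert len(kept & {"c1", "c2"}) == 1

    def test_decorrelated_table_unchanged(self):
        rng = np.random.default_rng(7)
        # orthogonal-ish columns at n=200 stay below the threshold
        table = _desc_table(rng.normal(size=(200, 5)))
        out = filter_intercorrelated(table)
        assert out.shape == table.shape

    def test_zero_threshold_keeps_exactly_one_column(self, rng):
        table = _desc_table(rng.normal(size=(15, 10)))
        out = filter_intercorrelated(table, r2_threshold=0.0)
        assert out.shape[1] - 1 == 1

    def test_target_relevance_decides_survivor(self, rng):
        x = rng.normal(size=50)
        noise = rng.normal(size=50) * 0.01
        table = _desc_table(np.column_stack([x + noise, x]), ["near", "exact"])
        y = 3 * x
        out = filter_intercorrelated(table, target=y)
        assert list(out.columns) == ["ligand_id", "exact"]

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_no_surviving_pair_above_threshold(self, seed):
        g = np.random.default_rng(seed)
        base = g.normal(size=(25, 4))
        # add columns correlated with the base ones
        extra = base[:, :2] + 0.1 * g.normal(size=(25, 2))
        table = _desc_table(np.column_stack([base, extra]))
        out = filter_intercorrelated(table, r2_threshold=0.64)
        cols = [c for c in out.columns if c != "ligand_id"]
        mat = out[cols].to_numpy()
        for i, j in itertools.combinations(range(len(cols)), 2):
            r2 = np.corrcoef(mat[:, i], mat[:, j])[0, 1] ** 2
            assert r2 < 0.64


class TestNormalizer:
    def test_simple_column(self):
        norm = Normalizer().fit(np.array([[1.0], [2.0], [3.0]]))
        out = norm.transform(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out.ravel(), [-1, 0, 1])

    def test_held_out_row_at_training_mean_maps_to_zero(self, rng):
        X = rng.normal(5, 3, size=(20, 4))
        norm = Normalizer().fit(X)
        z = norm.transform(X.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(z, 0, atol=1e-12)

    def test_inverse_round_trip(self, rng):
        X = rng.normal(size=(30, 5)) * rng.uniform(0.5, 4, 5)
        norm = Normalizer().fit(X)
        np.testing.assert_allclose(norm.inverse_transform(norm.transform(X)),
                                   X, atol=1e-12)

    def test_training_stats_independent_of_test_rows(self, rng):
        X = rng.normal(size=(25, 3))
        norm = Normalizer().fit(X)
        probe = rng.normal(size=(5, 3))
        z1 = norm.transform(probe)
        # refitting on the same training rows gives identical transforms
        z2 = Normalizer().fit(X.copy()).transform(probe)
        np.testing.assert_array_equal(z1, z2)

    def test_zero_sd_feature_rejected(self):
        with pytest.raises(ValueError, match="clean"):
            Normalizer().fit(np.column_stack([np.ones(5), np.arange(5.0)]))


class TestGfaSelect:
    def test_recovers_single_informative_descriptor(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 21))
        y = 2.0 * X[:, 7] + 0.1 * rng.normal(size=200)
        sel = gfa_select(X, y, population=30, generations=15,
                         subset_size_range=(1, 4), seed=3)
        assert 7 in sel

    def test_full_subset_is_identity(self, rng):
        X = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        sel = gfa_select(X, y, population=10, generations=3,
                         subset_size_range=(5, 5), seed=0)
        assert sorted(sel) == [0, 1, 2, 3, 4]

    def test_matches_exhaustive_best_pair(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(80, 6))
        y = X[:, 1] - 1.5 * X[:, 4] + 0.05 * rng.normal(size=80)
        sel = gfa_select(X, y, population=40, generations=30,
                         subset_size_range=(2, 2), seed=5)
        from docksel.prep import _cv_mse_fitness
        best = max(itertools.combinations(range(6), 2), key=lambda pair: (
            _cv_mse_fitness(X, y, np.isin(np.arange(6), pair), 5, 1.0, 5)))
        assert sorted(sel) == sorted(best)

    def test_oversized_range_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            gfa_select(rng.normal(size=(20, 3)), rng.normal(size=20),
                       subset_size_range=(2, 5), seed=0)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(50, 8))
        y = X[:, 2] + rng.normal(size=50)
        a = gfa_select(X, y, population=20, generations=5,
                       subset_size_range=(2, 4), seed=42)
        b = gfa_select(X, y, population=20, generations=5,
                       subset_size_range=(2, 4), seed=42)
        assert a == b


class TestRfeSelect:
    def test_keep_all_is_identity(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        sel, elim = rfe_select(X, y, n_keep=4)
        assert sel == [0, 1, 2, 3] and elim == []

    def test_single_signal_column_survives(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 5))
        y = 3 * X[:, 0] + 0.1 * rng.normal(size=100)
        sel, elim = rfe_select(X, y, n_keep=1)
        assert sel == [0]
        assert len(elim) == 4

    def test_output_subset_of_input(self, rng):
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        names = [f"d{j}" for j in range(6)]
        sel, elim = rfe_select(X, y, n_keep=3, feature_names=names)
        assert set(sel) <= set(names)
        assert len(sel) == 3
        assert set(sel) | set(elim) == set(names)


class TestKennardStone:
    def test_37_compounds_split_24_13(self, rng):
        X = rng.normal(size=(37, 8))
        res = kennard_stone_split(X, ratio=(2, 1))
        assert len(res.train_ids) == 24
        assert len(res.test_ids) == 13

    def test_hand_worked_1d_example(self):
        res = kennard_stone_split(np.array([0.0, 1, 2, 3, 4]), n_train=3)
        assert res.train_ids == [0, 4, 2]
        assert res.test_ids == [1, 3]

    def test_two_rows_one_each(self):
        res = kennard_stone_split(np.array([[0.0], [5.0]]), ratio=(1, 1))
        assert res.train_ids == [0]
        assert res.test_ids == [1]

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_partition_and_seed_pair_property(self, seed):
        g = np.random.default_rng(seed)
        n = int(g.integers(4, 30))
        X = g.normal(size=(n, int(g.integers(1, 5))))
        res = kennard_stone_split(X, ratio=(2, 1))
        assert sorted(res.train_ids + res.test_ids) == list(range(n))
        assert not (set(res.train_ids) & set(res.test_ids))
        # first two training points realize the global max pairwise distance
        from scipy.spatial.distance import cdist
        d = cdist(X, X)
        assert d[res.train_ids[0], res.train_ids[1]] == pytest.approx(d.max())


class TestSplitDiagnostics:
    def test_single_feature_first_pc_explains_everything(self, rng):
        desc = pd.DataFrame({"ligand_id": [f"L{i}" for i in range(12)],
                             "d0": rng.normal(size=12)})
        aff = pd.DataFrame({"ligand_id": desc["ligand_id"],
                            "pki": rng.uniform(3, 10, 12)})
        res = kennard_stone_split(desc[["d0"]].to_numpy(),
                                  ids=desc["ligand_id"].tolist())
        out = split_diagnostics(desc, aff, res)
        assert out["pc_variance_explained"][0] == pytest.approx(1.0)
        assert out["pki_summary"]["train"]["n"] == 8

    def test_isotropic_cloud_has_flat_spectrum(self):
        rng = np.random.default_rng(10)
        n, p = 4000, 3
        desc = pd.DataFrame(rng.normal(size=(n, p)),
                            columns=[f"d{j}" for j in range(p)])
        desc.insert(0, "ligand_id", [f"L{i}" for i in range(n)])
        aff = pd.DataFrame({"ligand_id": desc["ligand_id"],
                            "pki": rng.uniform(3, 10, n)})
        from docksel.prep import SplitResult
        split = SplitResult(train_ids=desc["ligand_id"][: 2 * n // 3].tolist(),
                            test_ids=desc["ligand_id"][2 * n // 3:].tolist(),
                            ratio=(2, 1))
        out = split_diagnostics(desc, aff, split)
        ratios = out["pc_variance_explained"]
        assert max(ratios) - min(ratios) < 0.1
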