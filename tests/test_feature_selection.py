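import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methorigin import (
    LabelledDataset,
    MFMDRanker,
    OmicsMatrix,
    differential_screen,
    euclidean_redundancy,
    f_statistic,
    f_statistics,
    generate_methylation,
    mfmd_rank,
    select_top_k,
)
from methorigin.feature_selection import F_CAP, _GRAM_THRESHOLD

from _oracles import oracle_euclidean_redundancy, oracle_f_statistic, oracle_mfmd
from conftest import random_labelled


class TestFStatistic:
    def test_hand_computed_anova(self):
        """Groups {1,2},{3,4},{5,6}: between SS 16 (df 2), within SS 1.5
        (df 3), so F = 8 / 0.5 = 16."""
        values = [1, 2, 3, 4, 5, 6]
        labels = ["a", "a", "b", "b", "c", "c"]
        assert f_statistic(values, labels) == pytest.approx(16.0)

    def test_agrees_with_scipy_f_oneway(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=30)
        labels = np.repeat(["a", "b", "c"], 10)
        expected = stats.f_oneway(values[:10], values[10:20], values[20:]).statistic
        assert f_statistic(values, labels) == pytest.approx(expected, rel=1e-12)

    def test_equal_group_means_give_near_zero(self):
        values = [1.0, 3.0, 1.0, 3.0, 1.0, 3.0]
        labels = ["a", "a", "b", "b", "c", "c"]
        assert f_statistic(values, labels) == pytest.approx(0.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=24)
        labels = np.repeat(["a", "b", "c"], 8)
        f0 = f_statistic(values, labels)
        perm = rng.permutation(24)
        assert f_statistic(values[perm], labels[perm]) == pytest.approx(f0, rel=1e-12)

    def test_degenerate_variances(self):
        # zero within, nonzero between -> finite cap
        assert f_statistic([1, 1, 2, 2], ["a", "a", "b", "b"]) == F_CAP
        # zero within and between -> 0
        assert f_statistic([2, 2, 2, 2], ["a", "a", "b", "b"]) == 0.0

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 6))
        y = np.repeat(["a", "b", "c", "d"], 5)
        vec = f_statistics(X, y)
        for j in range(6):
            assert vec[j] == pytest.approx(f_statistic(X[:, j], y), rel=1e-12)


class TestEuclideanRedundancy:
    def test_identical_features_have_zero_distance(self):
        v = np.linspace(0, 1, 8)
        X = np.column_stack([v, v])
        assert euclidean_redundancy(X) == pytest.approx([0.0, 0.0])

    def test_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(12, 5))
        np.testing.assert_array_equal(euclidean_redundancy(X), oracle_euclidean_redundancy(X))

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(size=(10, 4))
        np.testing.assert_allclose(
            euclidean_redundancy(X + 3.7), euclidean_redundancy(X), rtol=1e-9
        )

    def test_single_candidate_rejected(self):
        with pytest.raises(ValueError, match="single candidate"):
            euclidean_redundancy(np.ones((5, 1)))

    def test_gram_path_agrees_with_direct_path(self):
        """Above the size threshold the mean distances come from the BLAS
        Gram formulation; it must agree with the direct algorithm."""
        rng = np.random.default_rng(7)
        m = _GRAM_THRESHOLD + 8
        X = rng.uniform(size=(20, m))
        gram = euclidean_redundancy(X)
        direct = euclidean_redundancy(X[:, : _GRAM_THRESHOLD // 2])
        np.testing.assert_allclose(
            gram[: _GRAM_THRESHOLD // 2],
            oracle_euclidean_redundancy(X)[: _GRAM_THRESHOLD // 2],
            rtol=1e-9,
        )
        # direct path itself is exact against the oracle
        np.testing.assert_array_equal(
            direct, oracle_euclidean_redundancy(X[:, : _GRAM_THRESHOLD // 2])
        )


class TestDifferentialScreen:
    def test_constant_feature_never_selected(self, toy_dataset):
        vals = toy_dataset.matrix.values.copy()
        vals.loc["cg000"] = 0.5
        ds = LabelledDataset(OmicsMatrix(vals), toy_dataset.labels)
        res = differential_screen(ds, fdr_threshold=0.01)
        assert not res.selected.loc["cg000"].any()
        assert (res.p_value.loc["cg000"] == 1.0).all()

    def test_extreme_effect_is_selected(self):
        """One feature shifted by ten within-group SDs in one class is
        picked up at q < 0.01 among 200 features."""
        ds = generate_methylation(n_classes=6, n_per_class=100, n_features=200,
                                  n_markers_per_class=0, delta=0.0, seed=1)
        vals = ds.matrix.values.copy()
        target = "cg00001"
        in_a = (ds.labels == "C01").to_numpy()
        row = vals.loc[target].to_numpy().copy()
        row[in_a] = np.clip(row[in_a] + 10 * row.std(), 0, 1)
        vals.loc[target] = row
        res = differential_screen(LabelledDataset(OmicsMatrix(vals), ds.labels), 0.01)
        assert res.q_value.loc[target, "C01"] < 0.01
        assert target in res.selected_features()

    def test_q_values_dominate_p_values(self, toy_dataset):
        res = differential_screen(toy_dataset, 0.05)
        assert (res.q_value.to_numpy() >= res.p_value.to_numpy() - 1e-15).all()
        assert ((res.q_value.to_numpy() >= 0) & (res.q_value.to_numpy() <= 1)).all()

    def test_bh_monotone_within_class(self):
        rng = np.random.default_rng(9)
        ds = random_labelled(rng, n_features=50, n_samples=30)
        res = differential_screen(ds, 0.05)
        for cls in res.p_value.columns:
            order = res.p_value[cls].sort_values().index
            q_sorted = res.q_value[cls].loc[order].to_numpy()
            assert (np.diff(q_sorted) >= -1e-15).all()

    def test_masked_matrix_rejected(self, toy_dataset):
        vals = toy_dataset.matrix.values.copy()
        vals.iloc[0, 0] = np.nan
        ds = LabelledDataset(OmicsMatrix(vals), toy_dataset.labels)
        with pytest.raises(ValueError, match="missing"):
            differential_screen(ds, 0.01)

    def test_fdr_controlled_under_null(self):
        """Pure-null matrices: the mean number of selected features stays
        within the nominal bound (quick 10-seed version; the acceptance
        suite runs 100 seeds)."""
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ds = random_labelled(rng, n_features=500, n_samples=120, n_classes=6)
            res = differential_screen(ds, 0.01)
            counts.append(len(res.selected_features()))
        assert np.mean(counts) <= 500 * 0.01 * 6


class TestMFMDRank:
    def test_reduces_to_f_ranking_when_distances_equal(self):
        """Features with disjoint two-sample supports are exactly
        pairwise equidistant, so the distance term carries no signal and
        the ranking is by F alone (even at the minimum distance weight)."""
        supports = {"f0": [0, 1], "f1": [4, 5], "f2": [8, 9], "f3": [2, 6]}
        frame = pd.DataFrame(0.0, index=list(supports),
                             columns=[f"s{i}" for i in range(12)])
        for f, cols in supports.items():
            frame.iloc[frame.index.get_loc(f), cols] = 0.8
        labels = pd.Series(np.repeat(["a", "b", "c"], 4), index=frame.columns)
        ds = LabelledDataset(OmicsMatrix(frame), labels)
        table, ranking = mfmd_rank(ds, candidates=list(supports), w_s=1.0, w_d=0.01)
        assert table["ED"].nunique() == 1
        assert (table["ED_norm"] == 0.0).all()
        by_f = sorted(supports, key=lambda f: (-table.loc[f, "F"], f))
        assert ranking == by_f
        assert table["F"].nunique() > 1  # the check is not vacuous

    def test_dominance_is_respected(self):
        """A feature above another in both normalized scores outranks it
        for every valid weight pair."""
        rng = np.random.default_rng(11)
        ds = random_labelled(rng, n_features=15, n_samples=24)
        for w_s, w_d in [(1.0, 1.0), (0.3, 1.0), (1.0, 0.3), (0.5, 0.5)]:
            table, ranking = mfmd_rank(ds, candidates=list(ds.matrix.feature_ids),
                                       w_s=w_s, w_d=w_d)
            pos = {f: i for i, f in enumerate(ranking)}
            for fa in table.index:
                for fb in table.index:
                    if (table.loc[fa, "F_norm"] > table.loc[fb, "F_norm"]
                            and table.loc[fa, "ED_norm"] > table.loc[fb, "ED_norm"]):
                        assert pos[fa] < pos[fb]

    def test_matches_bruteforce_oracle_exactly(self):
        """20-feature instance: the whole score table and order equal the
        independent loop-based reimplementation, float for float."""
        rng = np.random.default_rng(12)
        ds = random_labelled(rng, n_features=20, n_samples=30)
        fids = list(ds.matrix.feature_ids)
        table, ranking = mfmd_rank(ds, candidates=fids, w_s=0.7, w_d=0.4)
        X, y = ds.to_xy()
        F, ED, F_norm, ED_norm, mfmd, order = oracle_mfmd(
            X.to_numpy(), y.to_numpy(), fids, 0.7, 0.4
        )
        expected_ranking = [fids[j] for j in order]
        assert ranking == expected_ranking
        lookup = {f: j for j, f in enumerate(fids)}
        for f in fids:
            j = lookup[f]
            assert table.loc[f, "F"] == F[j]
            assert table.loc[f, "ED"] == ED[j]
            assert table.loc[f, "mfmd"] == mfmd[j]

    def test_scale_equivariance(self):
        """Scaling the matrix by c > 0 leaves F untouched, scales ED by c,
        and preserves the normalized ranking."""
        rng = np.random.default_rng(13)
        ds = random_labelled(rng, n_features=12, n_samples=18)
        fids = list(ds.matrix.feature_ids)
        t1, r1 = mfmd_rank(ds, candidates=fids)
        scaled = LabelledDataset(
            OmicsMatrix(ds.matrix.values * 0.25), ds.labels
        )
        t2, r2 = mfmd_rank(scaled, candidates=fids)
        np.testing.assert_allclose(t2["F"].to_numpy(), t1["F"].to_numpy(), rtol=1e-9)
        np.testing.assert_allclose(t2["ED"].to_numpy(), 0.25 * t1["ED"].to_numpy(), rtol=1e-9)
        assert r1 == r2

    def test_invalid_weights_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="weights"):
            mfmd_rank(toy_dataset, candidates=list(toy_dataset.matrix.feature_ids), w_s=0.0)
        with pytest.raises(ValueError, match="weights"):
            mfmd_rank(toy_dataset, candidates=list(toy_dataset.matrix.feature_ids), w_d=1.5)

    def test_degenerate_normalization_collapses_to_zero(self):
        """Identical candidate rows: F and ED have no spread, so both
        normalized scores are defined as zero and every mfmd is zero."""
        v = np.linspace(0.1, 0.9, 12)
        frame = pd.DataFrame(
            [v, v, v], index=["a", "b", "c"], columns=[f"s{i}" for i in range(12)],
        )
        labels = pd.Series(np.repeat(["x", "y", "z"], 4), index=frame.columns)
        ds = LabelledDataset(OmicsMatrix(frame), labels)
        table, _ = mfmd_rank(ds, candidates=["a", "b", "c"])
        assert (table["F_norm"] == 0.0).all()
        assert (table["ED_norm"] == 0.0).all()
        assert (table["mfmd"] == 0.0).all()

    def test_ranker_transform_selects_top_features(self):
        rng = np.random.default_rng(14)
        ds = random_labelled(rng, n_features=20, n_samples=30)
        X, y = ds.to_xy()
        ranker = MFMDRanker(n_features=5, fdr_threshold=None).fit(X, y)
        out = ranker.transform(X)
        assert out.columns.tolist() == ranker.ranking_[:5]
        assert list(ranker.get_feature_names_out()) == ranker.ranking_[:5]

    def test_planted_markers_rank_high(self):
        """Quick recovery check: most of the top-ranked features on a
        small planted dataset are true markers (the acceptance suite runs
        the full-size version)."""
        ds = generate_methylation(n_classes=4, n_per_class=50, n_features=800,
                                  n_markers_per_class=20, delta=0.3, seed=21)
        _, ranking = mfmd_rank(ds)
        top = set(ranking[:80])
        assert len(top & ds.truth.all_markers()) / 80 >= 0.8


class TestSelectTopK:
    def test_full_length_is_identity(self):
        ranked = ["a", "b", "c"]
        assert select_top_k(ranked, 3) == ranked

    def test_singleton_is_maximum(self):
        rng = np.random.default_rng(15)
        ds = random_labelled(rng, n_features=10, n_samples=15)
        table, ranking = mfmd_rank(ds, candidates=list(ds.matrix.feature_ids))
        assert select_top_k(ranking, 1) == [table["mfmd"].idxmax()]

    def test_prefix_nesting(self):
        ranked = [f"f{i}" for i in range(100)]
        assert set(select_top_k(ranked, 10)) <= set(select_top_k(ranked, 50))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="k must lie"):
            select_top_k(["a", "b"], 3)
        with pytest.raises(ValueError, match="k must lie"):
            select_top_k(["a", "b"], 0)
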