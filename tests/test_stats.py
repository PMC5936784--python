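"""Welch tests, PLS-DA (fit/permutation/Q2), and heat-map matrices."""

import itertools

import numpy as np
import pandas as pd
import pytest

from scmetab.stats import (
    _benjamini_hochberg,
    differential_features,
    heatmap_data,
    plsda_fit,
    plsda_permutation_test,
    plsda_q2,
    separation_statistic,
    t_test_feature,
)

from conftest import make_matrix


class TestWelch:
    def test_textbook_example(self):
        t, df, p = t_test_feature([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(0.0213, abs=2e-4)

    def test_identical_samples(self):
        t, _, p = t_test_feature([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_degenerate_zero_variance(self):
        t, _, p = t_test_feature([2, 2], [2, 2])
        assert t == 0.0 and p == 1.0
        t, _, p = t_test_feature([3, 3], [2, 2])
        assert np.isinf(t) and p == 0.0

    def test_group_size_precondition(self):
        with pytest.raises(ValueError):
            t_test_feature([1], [2, 3])

    def test_matches_exact_permutation_test(self):
        """At n=4+4 the Welch p is close to the exact label-permutation p of
        the mean difference (brute force over all 70 splits)."""
        rng = np.random.default_rng(8)
        diffs = []
        for _ in range(10):
            pooled = rng.normal(0, 1, size=8)
            a, b = pooled[:4], pooled[4:]
            t_obs, _, p_welch = t_test_feature(a, b)
            count = 0
            splits = list(itertools.combinations(range(8), 4))
            for idx in splits:
                ga = pooled[list(idx)]
                gb = pooled[[i for i in range(8) if i not in idx]]
                t_perm, _, _ = t_test_feature(ga, gb)
                if abs(t_perm) >= abs(t_obs) - 1e-12:
                    count += 1
            p_exact = count / len(splits)
            diffs.append(abs(p_welch - p_exact))
            if p_exact < 0.2:  # tight where decisions happen
                assert abs(p_welch - p_exact) < 0.08
        # mid-range p may deviate more on a 70-point permutation grid at n=4
        assert np.mean(diffs) < 0.08 and max(diffs) < 0.25


class TestDifferential:
    def test_alpha_zero_yields_nothing(self, light_dark_sim):
        _, _, _, fm, _ = light_dark_sim
        assert differential_features(fm, alpha=0.0).n_significant == 0

    def test_constant_feature_flagged(self):
        fm = make_matrix([[1.0, 5.0], [1.0, 6.0], [1.0, 1.0], [1.0, 2.0]],
                         ["a", "a", "b", "b"])
        res = differential_features(fm)
        row = res.table.iloc[0]
        assert row["degenerate"] and row["p"] == 1.0

    def test_null_calibration(self):
        """Raw-p rejection rate on generator-shaped null data is ~alpha."""
        rng = np.random.default_rng(2)
        n, m = 15, 4000
        base = rng.normal(11, 1.2, size=m)
        X = np.exp(base + rng.normal(0, 0.5, size=(2 * n, m)))
        fm = make_matrix(X, ["a"] * n + ["b"] * n,
                         consensus_mz=np.linspace(100, 1500, m))
        rate = differential_features(fm, alpha=0.05).n_significant / m
        assert 0.03 < rate < 0.07

    def test_direction_counts_sum(self, light_dark_sim):
        _, _, _, fm, _ = light_dark_sim
        res = differential_features(fm)
        assert (res.n_significant_up_in("light") + res.n_significant_up_in("dark")
                == res.n_significant)


class TestPlsdaFit:
    def test_separable_single_feature(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-1, 0.1, 10), rng.normal(1, 0.1, 10)])
        fm = make_matrix(x[:, None], ["a"] * 10 + ["b"] * 10)
        res = plsda_fit(fm, n_components=1)
        s = res.scores[:, 0]
        assert max(s[:10]) < min(s[10:]) or min(s[:10]) > max(s[10:])

    def test_scores_zero_mean(self, light_dark_sim):
        _, _, _, fm, _ = light_dark_sim
        res = plsda_fit(fm)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_degenerate_matrix_rejected(self):
        fm = make_matrix(np.ones((6, 3)), ["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValueError, match="zero-variance|no covariance"):
            plsda_fit(fm, n_components=1)

    def test_component_cap(self):
        fm = make_matrix(np.random.default_rng(1).normal(size=(4, 5)),
                         ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="n_components"):
            plsda_fit(fm, n_components=4)

    def test_duplicating_all_columns_scales_scores(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 6))
        y = ["a"] * 5 + ["b"] * 5
        fm1 = make_matrix(X, y)
        fm2 = make_matrix(np.hstack([X, X]), y)
        s1 = plsda_fit(fm1, 2, scale="center").scores
        s2 = plsda_fit(fm2, 2, scale="center").scores
        np.testing.assert_allclose(s2, np.sqrt(2) * s1, atol=1e-8)

    def test_cell_order_invariance(self, light_dark_sim):
        _, _, _, fm, _ = light_dark_sim
        res1 = plsda_fit(fm)
        rng = np.random.default_rng(4)
        perm = rng.permutation(fm.n_cells)
        from scmetab.containers import FeatureMatrix

        fm2 = FeatureMatrix(
            values=fm.values.iloc[perm],
            consensus_mz=fm.consensus_mz,
            conditions=fm.conditions.iloc[perm],
        )
        res2 = plsda_fit(fm2)
        inv = np.argsort(perm)
        np.testing.assert_allclose(res2.scores[inv], res1.scores, atol=1e-8)

    def test_matches_sklearn_pls(self, light_dark_sim):
        """NIPALS/PLS1 predictions equal scikit-learn's PLS regression."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        _, _, _, fm, _ = light_dark_sim
        X = fm.values.to_numpy()
        y = np.where(fm.conditions.to_numpy() == "light", -1.0, 1.0)
        ours = plsda_fit(fm, 2, scale="center")
        ref = sklearn_pls.PLSRegression(n_components=2, scale=False).fit(X, y)
        np.testing.assert_allclose(
            ours.model.predict(X), ref.predict(X).ravel(), atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(ours.scores), np.abs(ref.x_scores_), atol=1e-6
        )


class TestPermutation:
    def test_seed_reproducibility(self, light_dark_sim):
        _, _, _, fm, _ = light_dark_sim
        p1 = plsda_permutation_test(fm, n_permutations=99, seed=5)
        p2 = plsda_permutation_test(fm, n_permutations=99, seed=5)
        assert p1 == p2

    def test_minimum_attainable_p(self, light_dark_sim):
        _, _, _, fm, _ = light_dark_sim
        p = plsda_permutation_test(fm, n_permutations=199, seed=0)
        assert p >= 1 / 200

    def test_pure_noise_p_moderate(self):
        rng = np.random.default_rng(6)
        ps = []
        for s in range(10):
            X = rng.normal(size=(16, 40))
            fm = make_matrix(X, ["a"] * 8 + ["b"] * 8)
            ps.append(plsda_permutation_test(fm, n_permutations=99, seed=s))
        assert 0.2 < np.mean(ps) < 0.8

    def test_permutation_count_precondition(self, light_dark_sim):
        _, _, _, fm, _ = light_dark_sim
        with pytest.raises(ValueError):
            plsda_permutation_test(fm, n_permutations=10)


class TestQ2:
    def test_separable_data_high_q2(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-1, 0.1, (10, 5)), rng.normal(1, 0.1, (10, 5))])
        fm = make_matrix(X, ["a"] * 10 + ["b"] * 10)
        assert plsda_q2(fm, seed=1) > 0.9

    def test_seed_reproducibility(self, light_dark_sim):
        _, _, _, fm, _ = light_dark_sim
        assert plsda_q2(fm, seed=3) == plsda_q2(fm, seed=3)

    def test_component_precondition(self):
        fm = make_matrix(np.random.default_rng(1).normal(size=(6, 8)),
                         ["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValueError):
            plsda_q2(fm, n_components=5)

    def test_fold_precondition(self, light_dark_sim):
        _, _, _, fm, _ = light_dark_sim
        with pytest.raises(ValueError):
            plsda_q2(fm, folds=1)


def test_separation_statistic_properties():
    y = np.array([-1.0, -1.0, 1.0, 1.0])
    tight = np.array([[-1.0], [-1.0], [1.0], [1.0]])
    loose = np.array([[-1.0], [1.0], [-1.0], [1.0]])
    assert separation_statistic(tight, y) > separation_statistic(loose, y)


def test_benjamini_hochberg_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.stats.multitest")
    rng = np.random.default_rng(0)
    p = rng.uniform(size=200) ** 2
    ours = _benjamini_hochberg(p)
    ref = sm.multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestHeatmap:
    def test_hand_computed_z_scores(self):
        fm = make_matrix([[1.0, 10.0], [3.0, 30.0]], ["a", "b"])
        hm = heatmap_data(fm, fm.feature_ids)
        np.testing.assert_allclose(hm.matrix.to_numpy(),
                                   [[-1.0, 1.0], [-1.0, 1.0]])

    def test_rows_standardized(self, light_dark_sim):
        _, _, _, fm, _ = light_dark_sim
        feats = fm.feature_ids[:20]
        hm = heatmap_data(fm, feats)
        m = hm.matrix.to_numpy()
        np.testing.assert_allclose(m.mean(axis=1), 0.0, atol=1e-10)
        sds = m.std(axis=1)
        assert np.all((np.abs(sds - 1) < 1e-9) | (sds == 0))

    def test_constant_feature_zero_row_last(self):
        vals = np.array([[1.0, 5.0], [1.0, 7.0], [1.0, 2.0]])
        fm = make_matrix(vals, ["a", "a", "b"])
        hm = heatmap_data(fm, fm.feature_ids)
        const_id = fm.feature_ids[0]
        assert hm.row_order[-1] == const_id
        assert (hm.matrix.loc[const_id] == 0).all()

    def test_cell_permutation_preserves_row_clustering(self, light_dark_sim):
        _, _, _, fm, _ = light_dark_sim
        feats = fm.feature_ids[:15]
        hm1 = heatmap_data(fm, feats)
        from scmetab.containers import FeatureMatrix

        perm = np.random.default_rng(2).permutation(fm.n_cells)
        fm2 = FeatureMatrix(values=fm.values.iloc[perm],
                            consensus_mz=fm.consensus_mz,
                            conditions=fm.conditions.iloc[perm])
        hm2 = heatmap_data(fm2, feats)
        # z-scores are cell-order invariant
        pd.testing.assert_frame_equal(hm1.matrix, hm2.matrix[hm1.matrix.columns])
        # trees are equivalent: identical merge heights (leaf order may flip
        # branches because float summation order perturbs exact ties)
        np.testing.assert_allclose(np.sort(hm1.row_linkage[:, 2]),
                                   np.sort(hm2.row_linkage[:, 2]), atol=1e-9)
        np.testing.assert_allclose(np.sort(hm1.col_linkage[:, 2]),
                                   np.sort(hm2.col_linkage[:, 2]), atol=1e-9)

    def test_empty_subset_rejected(self, light_dark_sim):
        _, _, _, fm, _ = light_dark_sim
        with pytest.raises(ValueError):
            heatmap_data(fm, [])
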