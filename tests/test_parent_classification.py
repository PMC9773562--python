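"""PCA contributions, descriptor weighting and the random forest report."""

import numpy as np
import pandas as pd
import pytest

from phenoprop import parent_classification as pc


def _feature_table(x):
    return pd.DataFrame(np.asarray(x, float), columns=[f"d{i}" for i in range(np.asarray(x).shape[1])])


def _with_exact_covariance(rng, n, corr):
    """Sample whose empirical correlation matrix is exactly ``corr``."""
    p = corr.shape[0]
    x = rng.normal(size=(n, p))
    x -= x.mean(0)
    # whiten empirically, then color with the target correlation
    cov = np.cov(x, rowvar=False, ddof=1)
    x = x @ np.linalg.inv(np.linalg.cholesky(cov)).T
    return x @ np.linalg.cholesky(corr).T


class TestPca:
    def test_two_perfectly_correlated_descriptors(self, rng):
        a = rng.normal(size=100)
        summary = pc.fit_pca(_feature_table(np.c_[a, 2 * a + 1]))
        assert summary.explained_variance_ratio["PC1"] == pytest.approx(1.0)
        assert np.allclose(summary.contributions["PC1"], [50.0, 50.0])

    def test_dominant_variance_descriptor_owns_pc1(self, rng):
        # after internal unit-scaling both descriptors are exchangeable, so
        # build near-orthogonal structure instead: PC1 mixes them equally,
        # and a third independent noise-free check uses raw loadings
        x = _with_exact_covariance(rng, 200, np.eye(2))
        summary = pc.fit_pca(_feature_table(x))
        # independent descriptors: each PC is one axis, contribution ~100
        assert summary.contributions.max(axis=0).min() == pytest.approx(100.0, abs=1e-6)

    def test_contributions_sum_to_100_per_pc(self, rng):
        summary = pc.fit_pca(_feature_table(rng.normal(size=(40, 6))))
        assert np.allclose(summary.contributions.sum(axis=0), 100.0, atol=1e-6)
        assert summary.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rank_deficient_warns(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        with pytest.warns(RuntimeWarning, match="rank"):
            summary = pc.fit_pca(_feature_table(np.c_[a, b, a + b]))
        assert summary.n_components == 2


class TestDescriptorWeights:
    def test_single_pc_weights_proportional_to_squared_loadings(self, rng):
        summary = pc.fit_pca(_feature_table(rng.normal(size=(50, 4))))
        w = pc.descriptor_weights(summary, retained=1)
        sq = summary.loadings["PC1"] ** 2
        assert np.allclose(w, sq / sq.sum())

    def test_equicorrelated_descriptors_get_equal_weights(self, rng):
        p, rho = 4, 0.8
        corr = np.full((p, p), rho) + (1 - rho) * np.eye(p)
        x = _with_exact_covariance(rng, 200, corr)
        summary = pc.fit_pca(_feature_table(x))
        # lambda_1 = 1 + (p-1) rho = 3.4 of 4 -> 85% >= 80%, one PC retained
        assert pc.retained_pcs(summary) == 1
        w = pc.descriptor_weights(summary)
        assert np.allclose(w, 0.25, atol=1e-9)

    def test_weights_sum_to_one(self, rng):
        summary = pc.fit_pca(_feature_table(rng.normal(size=(60, 7))))
        for retained in (1, 3, summary.n_components):
            assert pc.descriptor_weights(summary, retained).sum() == pytest.approx(
                1.0, abs=1e-9
            )


def _separable_data(rng, n=100, sep=10.0):
    x = rng.normal(size=(2 * n, 5))
    y = np.array(["a"] * n + ["b"] * n)
    x[n:, 0] += sep  # one descriptor carries all the separation
    return _feature_table(x), y


class TestForest:
    def test_separable_classes_low_oob_and_top_importance(self, rng):
        feats, y = _separable_data(rng)
        report = pc.train_forest(feats, y, seed=1)
        assert report.oob_error <= 2.0
        assert report.importance_mda.idxmax() == "d0"
        assert report.importance_gini.idxmax() == "d0"
        # confusion matrix conservation
        assert report.confusion.to_numpy().sum() == len(report.valid_index)
        counts = pd.Series(y[report.valid_index]).value_counts()
        for cls in report.classes:
            assert report.confusion.loc[cls].sum() == counts[cls]

    def test_permuted_labels_give_chance_error(self, rng):
        feats, y = _separable_data(rng)
        y_perm = rng.permutation(y)
        report = pc.train_forest(feats, y_perm, seed=2)
        # chance level for 2 balanced classes is 50%
        assert 38.0 <= report.oob_error <= 62.0

    def test_identical_seed_identical_report(self, rng):
        feats, y = _separable_data(rng, n=40)
        a = pc.train_forest(feats, y, seed=7)
        b = pc.train_forest(feats, y, seed=7)
        assert a.oob_error == b.oob_error
        pd.testing.assert_frame_equal(a.confusion, b.confusion)
        pd.testing.assert_series_equal(a.importance_mda, b.importance_mda)

    def test_duplicated_column_splits_gini(self, rng):
        feats, y = _separable_data(rng)
        single = pc.train_forest(feats, y, seed=3)
        dup = feats.copy()
        dup["d0_copy"] = dup["d0"]
        doubled = pc.train_forest(dup, y, seed=3)
        combined = doubled.importance_gini[["d0", "d0_copy"]].sum()
        assert combined == pytest.approx(single.importance_gini["d0"], rel=0.2)

    def test_small_class_rejected(self, rng):
        feats = _feature_table(rng.normal(size=(10, 3)))
        y = np.array(["a"] * 9 + ["b"])
        with pytest.raises(ValueError):
            pc.train_forest(feats, y)

    def test_pure_noise_descriptor_mda_within_null(self, rng):
        """MDA of a pure-noise descriptor stays below the 95th percentile of
        a permutation null of MDAs."""
        feats, y = _separable_data(rng, n=60)
        report = pc.train_forest(feats, y, seed=5)
        noise_mda = report.importance_mda["d3"]  # a pure-noise column
        null = []
        for s in range(8):
            null_report = pc.train_forest(feats, rng.permutation(y), seed=s)
            null.extend(null_report.importance_mda.to_numpy())
        assert noise_mda <= np.quantile(null, 0.95) + 1e-12


class TestSelectFeatures:
    def test_zero_thresholds_keep_everything_above_zero(self, rng):
        feats, y = _separable_data(rng, n=50)
        report = pc.train_forest(feats, y, seed=6)
        chosen = pc.select_features(report, 0.0, 0.0)
        assert "d0" in chosen
        assert chosen == sorted(
            chosen, key=lambda c: -report.importance_mda[c]
        )

    def test_impossible_thresholds_fall_back_to_top5(self, rng):
        feats, y = _separable_data(rng, n=50)
        report = pc.train_forest(feats, y, seed=6)
        with pytest.warns(RuntimeWarning, match="top 5"):
            chosen = pc.select_features(report, gini_min=1e9, mda_min=1e9)
        assert len(chosen) == 5 and chosen[0] == "d0"

    def test_separating_descriptor_always_selected(self, rng):
        feats, y = _separable_data(rng)
        for s in range(3):
            report = pc.train_forest(feats, y, seed=s)
            assert "d0" in pc.select_features(report, 0.0, 0.0)
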