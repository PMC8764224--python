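import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metaboresponse as mr
from metaboresponse.foldchange import FoldChangeMatrix


def _toy_fc(values, groups):
    idx = pd.Index([f"S{i}" for i in range(len(values))], name="subject_id")
    v = pd.DataFrame(values, index=idx,
                     columns=[f"f{j}" for j in range(np.shape(values)[1])])
    return FoldChangeMatrix(v, pd.Series(groups, index=idx), "toy")


class TestComputeFoldChanges:
    def test_doubling_gives_plus_one(self, toy_tables):
        fm, _ = mr.read_study(**toy_tables)
        fc = mr.compute_fold_changes(fm)
        # subject S1: FA1 100 -> 200
        assert fc.values.loc["S1", "FA1"] == pytest.approx(1.0)

    def test_no_change_gives_zero(self):
        fm, _, _ = mr.simulate_study(
            n_features=6, seed=0, effect=mr.EffectSpec.null(),
            noise=mr.NoiseSpec.null())
        fc = mr.compute_fold_changes(fm)
        assert np.abs(fc.values.to_numpy()).max() == 0.0

    def test_platform_grouping_concatenates(self, default_study):
        fm, _, _ = default_study
        plat = ["lipidRPCpos", "lipidRPCneg", "HILICpos"]
        fc = mr.compute_fold_changes(fm, platforms=plat)
        expect = fm.features["platform"].isin(plat).sum()
        assert fc.values.shape[1] == expect

    def test_unpaired_subject_dropped(self, default_study):
        fm, _, _ = default_study
        drop = fm.samples.index[fm.samples["timepoint"] == "week4"][0]
        fm2 = mr.FeatureMatrix(
            fm.samples.drop(index=drop), fm.features.copy(),
            fm.values.drop(index=drop))
        fc = mr.compute_fold_changes(fm2)
        assert len(fc.subjects) == len(fm.subjects) - 1


class TestPCA:
    def test_rank_one_matrix(self):
        rng = np.random.default_rng(0)
        fc = _toy_fc(np.outer(rng.normal(size=12), rng.normal(size=30)),
                     ["SAL"] * 6 + ["VLCD"] * 6)
        res = mr.FoldChangePCA(fc).fit()
        assert res.explained_variance_ratio.iloc[0] >= 0.999

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 7))
        fc = _toy_fc(X, ["SAL"] * 5 + ["VLCD"] * 5)
        res = mr.FoldChangePCA(fc, n_components=7).fit()
        Xc = X - X.mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.abs(recon - Xc).max() < 1e-8

    def test_eigendecomposition_oracle(self):
        """Explained-variance ratios agree with a covariance eigensolve."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 15))
        fc = _toy_fc(X, ["SAL"] * 12 + ["VLCD"] * 13)
        res = mr.FoldChangePCA(fc, n_components=10).fit()
        Xc = X - X.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(Xc, rowvar=False)))[::-1]
        expect = eig / eig.sum()
        assert np.abs(res.explained_variance_ratio.to_numpy()
                      - expect[:10]).max() < 1e-8

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 9))
        fc = _toy_fc(X, ["SAL"] * 10 + ["RYGB"] * 10)
        res = mr.FoldChangePCA(fc, n_components=5).fit()
        sk = PCA(n_components=5).fit(X)
        assert np.abs(res.explained_variance_ratio.to_numpy()
                      - sk.explained_variance_ratio_).max() < 1e-10

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(14, 8))
        groups = ["SAL"] * 7 + ["VLCD"] * 7
        fc = _toy_fc(X, groups)
        res = mr.FoldChangePCA(fc, n_components=3).fit()
        perm = rng.permutation(14)
        fc2 = FoldChangeMatrix(fc.values.iloc[perm], fc.groups.iloc[perm], "p")
        res2 = mr.FoldChangePCA(fc2, n_components=3).fit()
        pd.testing.assert_frame_equal(
            res.scores.loc[fc2.subjects], res2.scores, atol=1e-10, rtol=0)

    def test_constant_column_under_uv_warns(self):
        X = np.random.default_rng(5).normal(size=(8, 4))
        X[:, 2] = 3.0
        fc = _toy_fc(X, ["SAL"] * 4 + ["VLCD"] * 4)
        with pytest.warns(UserWarning, match="constant"):
            mr.FoldChangePCA(fc, n_components=2, preprocessing="center_uv").fit()


class TestScoreGroupTests:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(16, 5))
        fc = _toy_fc(X, ["SAL"] * 8 + ["VLCD"] * 8)
        res = mr.FoldChangePCA(fc, n_components=2).fit()
        tab = res.group_tests()
        for comp in ("PC1", "PC2"):
            sub = tab[tab["component"] == comp]
            F = sub.loc[sub["test"] == "anova", "statistic"].iloc[0]
            x = res.scores[comp]
            t, _ = stats.ttest_ind(x[:8], x[8:], equal_var=True)
            assert F == pytest.approx(t**2, abs=1e-10)

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 6))
        X[:5] += 10.0  # one group shifted 10 SDs along every feature
        fc = _toy_fc(X, ["RYGB"] * 5 + ["SAL"] * 5 + ["VLCD"] * 5 + ["GOP"] * 5)
        tab = mr.FoldChangePCA(fc, n_components=2).fit().group_tests()
        rygb = tab[(tab["component"] == "PC1")
                   & tab["test"].str.contains("RYGB")]
        assert (rygb["p"] < 1e-4).all()

    def test_small_group_excluded(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(9, 4))
        fc = _toy_fc(X, ["SAL"] * 4 + ["VLCD"] * 4 + ["GOP"])
        with pytest.warns(UserWarning, match="excluding"):
            tab = mr.FoldChangePCA(fc, n_components=2).fit().group_tests()
        assert not tab["test"].str.contains("GOP").any()

    def test_null_pvalues_roughly_uniform(self):
        """No group structure: PC1 ANOVA p over replicates ~ U(0,1)."""
        rng = np.random.default_rng(9)
        groups = np.repeat(["SAL", "GOP", "VLCD", "RYGB"], 6)
        ps = []
        for _ in range(150):
            fc = _toy_fc(rng.normal(size=(24, 10)), groups)
            tab = mr.FoldChangePCA(fc, n_components=1).fit().group_tests()
            ps.append(tab.loc[tab["test"] == "anova", "p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01
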