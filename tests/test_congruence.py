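import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metaboresponse as mr
from metaboresponse.congruence import (
    clinical_correlations,
    mean_fold_changes,
    pairwise_congruence,
)
from metaboresponse.foldchange import FoldChangeMatrix


def _fc(values, groups):
    idx = pd.Index([f"S{i}" for i in range(len(values))], name="subject_id")
    v = pd.DataFrame(values, index=idx,
                     columns=[f"f{j}" for j in range(np.shape(values)[1])])
    return FoldChangeMatrix(v, pd.Series(groups, index=idx), "toy")


class TestMeanFoldChanges:
    def test_all_zero_matrix(self):
        fc = _fc(np.zeros((8, 3)), ["SAL"] * 4 + ["VLCD"] * 4)
        m = mean_fold_changes(fc)
        assert (m["mean"] == 0).all()
        assert (m["ci_low"] <= 0).all() and (m["ci_high"] >= 0).all()

    def test_ci_width_formula(self):
        rng = np.random.default_rng(0)
        fc = _fc(rng.normal(size=(12, 4)), ["SAL"] * 5 + ["VLCD"] * 7)
        m = mean_fold_changes(fc).set_index(["feature_id", "group"])
        for g, n in (("SAL", 5), ("VLCD", 7)):
            block = fc.values[fc.groups == g]
            sd = block.std(axis=0, ddof=1)
            width = 2 * stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
            got = (m.xs(g, level="group")["ci_high"]
                   - m.xs(g, level="group")["ci_low"])
            assert np.allclose(got, width.loc[got.index])

    def test_group_label_equivariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        g1 = ["SAL"] * 5 + ["VLCD"] * 5
        g2 = ["VLCD"] * 5 + ["SAL"] * 5
        m1 = mean_fold_changes(_fc(X, g1)).set_index(["feature_id", "group"])
        m2 = mean_fold_changes(_fc(X, g2)).set_index(["feature_id", "group"])
        assert np.allclose(m1.xs("SAL", level="group")["mean"],
                           m2.xs("VLCD", level="group")["mean"])

    def test_small_group_rejected(self):
        fc = _fc(np.zeros((3, 2)), ["SAL", "SAL", "VLCD"])
        with pytest.raises(mr.StudyError):
            mean_fold_changes(fc)


def _contrasts(features, q_vlcd, q_rygb, q_gop=None):
    rows = []
    for g, qs in (("VLCD", q_vlcd), ("RYGB", q_rygb),
                  ("GOP", q_gop if q_gop is not None else [1.0] * len(features))):
        for f, q in zip(features, qs):
            rows.append({"feature_id": f, "pair": f"{g}_vs_SAL", "q": q})
    return pd.DataFrame(rows)


class TestPairwiseCongruence:
    def test_identical_effects_r_one(self):
        rng = np.random.default_rng(2)
        eff = rng.normal(size=30)
        X = np.vstack([np.tile(eff, (5, 1)), np.tile(eff, (5, 1)),
                       np.zeros((5, 30)), np.zeros((5, 30))])
        fc = _fc(X, ["VLCD"] * 5 + ["RYGB"] * 5 + ["SAL"] * 5 + ["GOP"] * 5)
        means = mean_fold_changes(fc)
        feats = fc.features.tolist()
        rep = pairwise_congruence(means, _contrasts(feats, [1] * 30, [1] * 30))
        r = rep.pair_r.set_index("pair").loc["VLCD_vs_RYGB", "r"]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_categories_partition(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 6))
        fc = _fc(X, ["VLCD"] * 2 + ["RYGB"] * 2 + ["SAL"] * 2 + ["GOP"] * 2)
        feats = fc.features.tolist()
        con = _contrasts(feats,
                         [0.01, 0.01, 1, 1, 1, 1],
                         [0.01, 1, 0.01, 1, 1, 1],
                         [1, 1, 1, 0.01, 1, 1])
        rep = pairwise_congruence(mean_fold_changes(fc), con)
        assert rep.categories.loc["f0"] == "shared"
        assert rep.categories.loc["f1"] == "unique_VLCD"
        assert rep.categories.loc["f2"] == "unique_RYGB"
        assert rep.categories.loc["f3"] == "unique_GOP"
        assert rep.categories.loc["f4"] == "nonsignificant"
        assert set(rep.categories.unique()) <= {
            "shared", "unique_VLCD", "unique_RYGB", "unique_GOP",
            "nonsignificant"}

    def test_r_symmetric_and_small_subset_na(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 5))
        fc = _fc(X, ["VLCD"] * 2 + ["RYGB"] * 2 + ["SAL"] * 2 + ["GOP"] * 2)
        feats = fc.features.tolist()
        rep = pairwise_congruence(mean_fold_changes(fc),
                                  _contrasts(feats, [1] * 5, [1] * 5))
        wide = mean_fold_changes(fc).pivot(index="feature_id",
                                           columns="group", values="mean")
        r_direct = np.corrcoef(wide["VLCD"], wide["RYGB"])[0, 1]
        r = rep.pair_r.set_index("pair").loc["VLCD_vs_RYGB", "r"]
        assert r == pytest.approx(r_direct)
        # all features nonsignificant -> shared subset empty -> r is NA
        sub = rep.subset_r.set_index("category")
        assert np.isnan(sub.loc["shared", "r"])


class TestClinicalCorrelations:
    def _study(self, seed=0, link=None):
        fm, clin, _ = mr.simulate_study(
            n_features=40, seed=seed, effect=mr.EffectSpec.null(),
            clinical_link=link or {})
        return mr.compute_fold_changes(fm), clin

    def test_verbatim_factor_r_one(self):
        fc, clin = self._study(seed=5)
        v = fc.values.copy()
        v.iloc[:, 0] = clin.factor("weight").loc[v.index].to_numpy()
        fc2 = FoldChangeMatrix(v, fc.groups, "toy")
        tab = clinical_correlations(fc2, clin, scope="cohort")
        row = tab[(tab.feature_id == v.columns[0])
                  & (tab.factor == "delta_weight")]
        assert row["r"].iloc[0] == pytest.approx(1.0)

    def test_linked_feature_recovered(self):
        hits = 0
        for seed in range(10):
            fc, clin = self._study(seed=seed,
                                   link={"PF0000": ("weight", 0.3)})
            tab = clinical_correlations(fc, clin, scope="cohort")
            row = tab[(tab.feature_id == "PF0000")
                      & (tab.factor == "delta_weight")]
            if row["display"].iloc[0] and row["r"].iloc[0] > 0:
                hits += 1
        assert hits >= 9

    def test_null_false_positive_rate(self):
        rates = []
        for seed in range(5):
            fc, clin = self._study(seed=100 + seed)
            tab = clinical_correlations(fc, clin, scope="cohort",
                                        factors=["delta_weight"])
            rates.append(tab["display"].mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.04)

    def test_per_group_scope(self):
        fc, clin = self._study(seed=6)
        tab = clinical_correlations(fc, clin, scope="per-group",
                                    factors=["delta_weight"])
        assert set(tab["scope"].unique()) == {"SAL", "GOP", "VLCD", "RYGB"}

    def test_fdr_column_optional(self):
        fc, clin = self._study(seed=7)
        tab = clinical_correlations(fc, clin, fdr=True,
                                    factors=["delta_weight"])
        assert (tab["q"] >= tab["p"] - 1e-12).all()
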