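import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metaboresponse as mr
from metaboresponse.lme import bh_fdr, power_simulation, _build_design

from oracles import bh_stepup_reference, gls_grid_reml


class TestBHFDR:
    def test_hand_worked_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert (bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_nan_propagates_and_excluded_from_m(self):
        q = bh_fdr([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], bh_fdr([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_matches_stepup_definition_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            q = bh_fdr(p)
            assert np.allclose(q, bh_stepup_reference(p))
            assert np.allclose(q, multipletests(p, method="fdr_bh")[1])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestLMEFit:
    def test_zero_noise_null_betas_zero(self):
        fm, _, _ = mr.simulate_study(
            n_features=5, seed=0, effect=mr.EffectSpec.null(),
            noise=mr.NoiseSpec.null())
        res = mr.InteractionMixedLM(fm).fit()
        inter = [c for c in res.param_names if c.startswith("time")]
        cols = [res.param_names.index(c) for c in inter]
        assert np.abs(res.params[:, cols]).max() < 1e-10

    def test_balanced_contrast_equals_mean_paired_diff(self, default_study):
        """Interaction contrast g vs SAL = mean_g(dlog y) - mean_SAL(dlog y)."""
        fm, _, _ = default_study
        res = mr.InteractionMixedLM(fm).fit()
        con = res.contrasts("vs_sal").set_index(["feature_id", "pair"])
        y = fm.log_values(base=np.e)
        s = fm.samples.reset_index()
        b = s[s.timepoint == "baseline"].set_index("subject_id")
        w = s[s.timepoint == "week4"].set_index("subject_id")
        D = pd.DataFrame(
            y.loc[w["sample_id"]].to_numpy() - y.loc[b["sample_id"]].to_numpy(),
            index=b.index, columns=y.columns)
        groups = b["group"]
        for g in ("GOP", "VLCD", "RYGB"):
            expect = D[groups == g].mean() - D[groups == "SAL"].mean()
            got = con.xs(f"{g}_vs_SAL", level="pair")["estimate"]
            assert np.abs(got - expect.loc[got.index]).max() < 1e-8

    def test_closed_form_matches_profile(self):
        fm, _, _ = mr.simulate_study(n_features=8, seed=13)
        m = mr.InteractionMixedLM(fm)
        cf, pr = m.fit(method="closed_form"), m.fit(method="profile")
        assert np.abs(cf.params - pr.params).max() < 1e-8
        assert np.abs(cf.sigma2_resid - pr.sigma2_resid).max() < 1e-8
        assert np.abs(cf.sigma2_subject - pr.sigma2_subject).max() < 1e-8
        assert np.abs(cf.reml_loglik - pr.reml_loglik).max() < 1e-8

    @pytest.mark.parametrize("sizes", [
        {"SAL": 3, "VLCD": 3},
        {"SAL": 3, "GOP": 3, "VLCD": 4, "RYGB": 4},
    ])
    def test_matches_gls_grid_oracle(self, sizes):
        """REML agrees with a dense GLS-over-lambda brute force to 1e-6."""
        fm, _, _ = mr.simulate_study(n_per_group=sizes, n_features=4, seed=7)
        m = mr.InteractionMixedLM(fm)
        res = m.fit()
        X, _, subj, _, _ = _build_design(fm.samples)
        Y = fm.log_values(base=np.e).to_numpy()
        for j in range(Y.shape[1]):
            beta, s2b, s2e, lam, ll = gls_grid_reml(Y[:, j], X, subj)
            assert np.abs(res.params[j] - beta).max() < 1e-6
            assert res.sigma2_resid[j] == pytest.approx(s2e, abs=1e-6)
            assert res.sigma2_subject[j] == pytest.approx(s2b, abs=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        fm, _, _ = mr.simulate_study(
            n_per_group={"SAL": 5, "GOP": 5, "VLCD": 6, "RYGB": 6},
            n_features=3, seed=17)
        res = mr.InteractionMixedLM(fm).fit()
        df = fm.samples.copy()
        df["time"] = (df["timepoint"] == "week4").astype(float)
        df["group"] = pd.Categorical(df["group"],
                                     categories=["SAL", "GOP", "VLCD", "RYGB"])
        Y = fm.log_values(base=np.e)
        for j, fid in enumerate(Y.columns):
            df["y"] = Y[fid].to_numpy()
            sm = smf.mixedlm("y ~ time * group", df,
                             groups=df["subject_id"]).fit(reml=True)
            fit = res.fit_for(fid)
            for name, smname in [("time", "time"),
                                 ("time:group[VLCD]", "time:group[T.VLCD]")]:
                assert fit.params[name] == pytest.approx(
                    sm.fe_params[smname], abs=1e-6)
            assert fit.sigma2_resid == pytest.approx(sm.scale, abs=1e-5)
            assert fit.sigma2_subject == pytest.approx(
                float(sm.cov_re.iloc[0, 0]), abs=1e-5)

    def test_scale_invariance_shifts_only_intercept(self, default_study):
        fm, _, _ = default_study
        res = mr.InteractionMixedLM(fm).fit()
        v2 = fm.values * 7.5
        fm2 = mr.FeatureMatrix(fm.samples.copy(), fm.features.copy(), v2)
        res2 = mr.InteractionMixedLM(fm2).fit()
        i = res.param_names.index("Intercept")
        other = [j for j in range(len(res.param_names)) if j != i]
        assert np.abs(res.params[:, other] - res2.params[:, other]).max() < 1e-10
        assert np.allclose(res2.params[:, i] - res.params[:, i], np.log(7.5))

    def test_row_permutation_invariance(self, default_study):
        fm, _, _ = default_study
        perm = np.random.default_rng(0).permutation(len(fm.samples))
        fm2 = mr.FeatureMatrix(fm.samples.iloc[perm], fm.features.copy(),
                               fm.values.iloc[perm])
        r1 = mr.InteractionMixedLM(fm).fit()
        r2 = mr.InteractionMixedLM(fm2).fit()
        assert np.abs(r1.params - r2.params).max() < 1e-10

    def test_boundary_sigma_subject_zero_flagged(self):
        """Between-subject variance below within-noise floor -> boundary fit."""
        fm, _, _ = mr.simulate_study(
            n_features=30, seed=2,
            noise=mr.NoiseSpec(sigma_subject=0.0, sigma_resid=0.5))
        res = mr.InteractionMixedLM(fm).fit()
        assert res.boundary.any()
        assert (res.sigma2_subject >= 0).all()


class TestContrasts:
    def test_antisymmetry(self, default_study):
        fm, _, _ = default_study
        res = mr.InteractionMixedLM(fm).fit()
        a = res.contrasts([("VLCD", "RYGB")])
        b = res.contrasts([("RYGB", "VLCD")])
        assert np.allclose(a["estimate"], -b["estimate"])
        assert np.allclose(a["p"], b["p"], equal_nan=True)

    def test_absent_group_errors(self, default_study):
        fm, _, _ = default_study
        res = mr.InteractionMixedLM(fm).fit()
        with pytest.raises(mr.StudyError):
            res.contrasts([("VLCD", "XXX")])

    def test_all_pairs_count(self, default_study):
        fm, _, _ = default_study
        res = mr.InteractionMixedLM(fm).fit()
        con = res.contrasts("all_pairs")
        assert con["pair"].nunique() == 6

    def test_q_at_least_p(self, default_study):
        fm, _, _ = default_study
        con = mr.InteractionMixedLM(fm).fit().contrasts("vs_sal")
        assert (con["q"] >= con["p"] - 1e-12).all()


class TestAdjustedModel:
    def test_zero_factor_reproduces_unadjusted(self, default_study):
        fm, _, _ = default_study
        sub = fm.subjects
        zero = pd.Series(0.0, index=sub)
        with pytest.warns(UserWarning, match="collinear"):
            adj = mr.InteractionMixedLM(fm, adjust_factor=zero).fit()
        un = mr.InteractionMixedLM(fm).fit()
        ca = adj.contrasts("vs_sal").set_index(["feature_id", "pair"])
        cu = un.contrasts("vs_sal").set_index(["feature_id", "pair"])
        assert np.abs(ca["estimate"] - cu["estimate"]).max() < 1e-10

    def test_three_way_columns_added(self, default_study):
        fm, clin, _ = default_study
        # a factor with within-group variance keeps all 4 extra columns
        m = mr.InteractionMixedLM(fm, adjust_factor=clin.factor("weight"))
        extra = [c for c in m._names if c.endswith(":factor")]
        assert len(extra) == 4
        assert np.linalg.matrix_rank(m._X) == m._X.shape[1]

    def test_weight_linked_feature_loses_significance(self):
        """A purely weight-driven feature is explained away by adjustment."""
        hits_un, hits_adj = 0, 0
        n_seeds = 25
        for seed in range(n_seeds):
            fm, clin, _ = mr.simulate_study(
                n_features=40, seed=seed, effect=mr.EffectSpec.null(),
                clinical_link={"PF0000": ("weight", 0.25)})
            if "PF0000" not in fm.features.index:
                continue
            un = mr.InteractionMixedLM(fm).fit()
            adj = mr.InteractionMixedLM(
                fm, adjust_factor=clin.factor("weight")).fit()
            cu = un.contrasts("vs_sal").set_index(["feature_id", "pair"])
            ca = adj.contrasts("vs_sal").set_index(["feature_id", "pair"])
            key = ("PF0000", "VLCD_vs_SAL")
            if cu.loc[key, "q"] < 0.05:
                hits_un += 1
                if not ca.loc[key, "q"] < 0.05:
                    hits_adj += 1
        assert hits_un > 0
        assert hits_adj / hits_un >= 0.8


class TestPowerSimulation:
    def _fc(self, seed=0, delta=None, n_features=60):
        eff = mr.EffectSpec.null() if delta is None else mr.EffectSpec(
            delta=delta, sal_drift_sd=0.0)
        fm, _, _ = mr.simulate_study(n_features=n_features, seed=seed, effect=eff)
        return mr.compute_fold_changes(fm), fm

    def test_null_generator_mean_count_near_zero(self):
        fc, _ = self._fc(seed=1)
        out = power_simulation(fc, target_group="GOP", target_n=14, B=40, seed=0)
        assert out["mean"] < 1.0

    def test_monotone_in_target_n(self):
        idx = [f"PF{i:04d}" for i in range(60)]
        delta = pd.DataFrame(0.0, index=idx, columns=["GOP"])
        delta.iloc[:20, 0] = 0.35
        fc, _ = self._fc(seed=3, delta=delta)
        means = [power_simulation(fc, "GOP", n, B=60, seed=0)["mean"]
                 for n in (14, 21, 28)]
        assert means[0] <= means[1] <= means[2]

    def test_small_b_warns(self):
        fc, _ = self._fc(seed=1, n_features=10)
        with pytest.warns(UserWarning, match="bootstrap"):
            power_simulation(fc, "GOP", 14, B=5, seed=0)

    def test_target_n_below_current_rejected(self):
        fc, _ = self._fc(seed=1, n_features=10)
        with pytest.raises(mr.StudyError):
            power_simulation(fc, "GOP", 5, B=20, seed=0)
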