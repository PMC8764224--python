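import numpy as np
import pandas as pd
import pytest

import metaboresponse as mr
from metaboresponse.pls import (
    PLSRegression1,
    _center_scale,
    q2y_cv,
    select_n_components,
)

from oracles import pls1_first_weight


def _xy(seed=42, n=30, p=12, noise=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(scale=noise, size=n)
    return (pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]),
            pd.Series(y, name="y"))


class TestFit:
    def test_first_weight_is_cross_covariance_direction(self):
        X, y = _xy()
        res = PLSRegression1(X, y, n_components=1).fit()
        v = pls1_first_weight(X.to_numpy(), y.to_numpy())
        w = res.weights.iloc[:, 0].to_numpy()
        cos = abs(w @ v) / np.linalg.norm(w)
        assert cos > 0.999

    def test_exact_fit_single_column_signal(self):
        # distractor columns orthogonalised against y so one component
        # suffices for the noiseless limit
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        y = X[:, 2].copy()
        yc = y - y.mean()
        for j in (0, 1, 3, 4):
            x = X[:, j] - X[:, j].mean()
            X[:, j] = x - (x @ yc) / (yc @ yc) * yc
        res = PLSRegression1(pd.DataFrame(X), pd.Series(3.0 * y),
                             n_components=1).fit()
        assert res.r2y > 0.999

    def test_matches_sklearn_reference(self):
        from sklearn.cross_decomposition import PLSRegression

        X, y = _xy(seed=42)
        res = PLSRegression1(X, y, n_components=3).fit()
        sk = PLSRegression(n_components=3, scale=True).fit(X, y)
        assert np.abs(res.predict(X) - sk.predict(X).ravel()).max() < 1e-6

    def test_scores_orthogonal(self):
        X, y = _xy(seed=1, n=25, p=40)
        T = PLSRegression1(X, y, n_components=4).fit().scores.to_numpy()
        G = T.T @ T
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8

    def test_deflation_shrinks_x_residual(self):
        from metaboresponse.pls import _nipals_pls1

        X, y = _xy(seed=2, n=20, p=8)
        Xc, yc, *_ = _center_scale(X.to_numpy(), y.to_numpy())
        norms = []
        Xd = Xc.copy()
        for k in range(1, 5):
            W, P, T, c, b = _nipals_pls1(Xc, yc, k)
            norms.append(np.linalg.norm(Xc - T @ P.T))
        assert all(np.diff(norms) < 0)

    def test_constant_y_rejected(self):
        X, _ = _xy()
        with pytest.raises(ValueError, match="zero variance"):
            PLSRegression1(X, pd.Series(np.ones(len(X))), n_components=1)

    def test_deterministic(self):
        X, y = _xy(seed=3)
        a = PLSRegression1(X, y, n_components=2, seed=5).fit()
        b = PLSRegression1(X, y, n_components=2, seed=5).fit()
        assert a.q2y == b.q2y
        pd.testing.assert_frame_equal(a.weights, b.weights)


class TestQ2:
    def test_noiseless_loo_approaches_one(self):
        X, y = _xy(seed=4, n=24, p=4, noise=0.0)
        q2 = q2y_cv(X.to_numpy(), y.to_numpy(), 4, folds=24, seed=0)
        assert q2 > 0.99

    def test_q2_not_above_r2_noiseless(self):
        X, y = _xy(seed=5, n=30, p=6, noise=0.0)
        res = PLSRegression1(X, y, n_components=4).fit()
        assert res.q2y <= res.r2y + 1e-6

    def test_null_mean_q2_nonpositive(self):
        q2s = []
        for s in range(60):
            rng = np.random.default_rng(s)
            q2s.append(q2y_cv(rng.normal(size=(40, 30)),
                              rng.normal(size=40), 2, folds=7, seed=s))
        assert np.mean(q2s) <= 0.0

    def test_noise_columns_degrade_q2_on_average(self):
        diffs = []
        for s in range(20):
            X, y = _xy(seed=100 + s, n=30, p=5, noise=1.0)
            rng = np.random.default_rng(s)
            Xn = pd.concat([X, pd.DataFrame(
                rng.normal(size=(30, 60)),
                columns=[f"n{i}" for i in range(60)])], axis=1)
            q_base = q2y_cv(X.to_numpy(), y.to_numpy(), 2, folds=7, seed=s)
            q_noise = q2y_cv(Xn.to_numpy(), y.to_numpy(), 2, folds=7, seed=s)
            diffs.append(q_noise - q_base)
        assert np.mean(diffs) < 0

    def test_fold_validation(self):
        X, y = _xy()
        with pytest.raises(ValueError):
            q2y_cv(X.to_numpy(), y.to_numpy(), 2, folds=1)
        with pytest.raises(ValueError):
            q2y_cv(X.to_numpy(), y.to_numpy(), 2, folds=len(y) + 1)


class TestPermutation:
    def test_perm_p_lower_bound(self):
        X, y = _xy(seed=6, n=40, p=10, noise=0.1)
        res = PLSRegression1(X, y, n_components=2).fit()
        rep = res.permutation_test(B=99, seed=0)
        assert rep.perm_p == pytest.approx(1.0 / 100.0)

    def test_strong_feature_empirical_p_floor(self):
        rng = np.random.default_rng(7)
        t = rng.normal(size=50)
        X = pd.DataFrame({"hit": t + 0.05 * rng.normal(size=50)})
        for i in range(9):
            X[f"n{i}"] = rng.normal(size=50)
        y = pd.Series(t + 0.05 * rng.normal(size=50))
        res = PLSRegression1(X, y, n_components=1).fit()
        rep = res.permutation_test(B=199, seed=1)
        assert rep.feature_table.loc["hit", "empirical_p"] == \
            pytest.approx(1.0 / 200.0)

    def test_invalid_model_selects_nothing(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(30, 20)))
        y = pd.Series(rng.normal(size=30))
        res = PLSRegression1(X, y, n_components=2).fit()
        rep = res.permutation_test(B=50, seed=0)
        assert not rep.valid
        assert rep.select_features() == []

    def test_b_must_be_positive(self):
        X, y = _xy()
        res = PLSRegression1(X, y, n_components=1).fit()
        with pytest.raises(ValueError):
            res.permutation_test(B=0)


def test_component_selection_prefers_true_dimension():
    rng = np.random.default_rng(9)
    n = 60
    t1, t2 = rng.normal(size=n), rng.normal(size=n)
    load1, load2 = rng.normal(size=30), rng.normal(size=30)
    X = np.outer(t1, load1) + np.outer(t2, load2) + 0.3 * rng.normal(size=(n, 30))
    y = 2 * t1 + t2 + 0.2 * rng.normal(size=n)
    k = select_n_components(X, y, kmax=5, folds=7, seed=0)
    assert 2 <= k <= 3
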