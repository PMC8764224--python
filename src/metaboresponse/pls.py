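"""PLS regression of metabolite blocks on clinical factors.

Single-y (PLS1) NIPALS with column centering and unit-variance scaling, the
chemometrics convention for metabolomic data. Model quality is the
cross-validated predicted-variance statistic Q2 = 1 - PRESS/TSS with all
preprocessing refit inside each training fold. Validity is established by
permutation: the full pipeline (fit + CV) is rerun on B mismatched-Y
permutations and the model counts as valid when Q2 > 0.15 and the
permutation p-value is below 0.01. For valid models, features associated
with the factor are selected empirically by comparing each true
first-component weight against its permutation null distribution
(add-one estimator; |weight|, two-sided by default).

Everything here is deterministic given (data, seed): NIPALS PLS1 needs no
random initialisation and CV fold assignment is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLSRegression1",
    "PLSResults",
    "PermutationReport",
    "q2y_cv",
    "select_n_components",
]


def _center_scale(X: np.ndarray, y: np.ndarray):
    xm = X.mean(axis=0)
    xs = X.std(axis=0, ddof=1)
    xs = np.where(xs == 0, 1.0, xs)
    ym = y.mean()
    return (X - xm) / xs, y - ym, xm, xs, ym


def _nipals_pls1(X: np.ndarray, y: np.ndarray, k: int):
    """NIPALS PLS1 on preprocessed data; deflation of X per component.

    Returns weights W (p x k), X-loadings P, y-loadings c (k), scores
    T (n x k) and the regression vector b mapping preprocessed X to
    centered y.
    """
    n, p = X.shape
    Xd = X.copy()
    yd = y.astype(float).copy()
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    T = np.zeros((n, k))
    c = np.zeros(k)
    for a in range(k):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            k = a
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            k = a
            break
        pvec = Xd.T @ t / tt
        ca = float(yd @ t) / tt
        W[:, a], P[:, a], T[:, a], c[a] = w, pvec, t, ca
        Xd -= np.outer(t, pvec)
        yd = yd - ca * t
    W, P, T, c = W[:, :k], P[:, :k], T[:, :k], c[:k]
    if k == 0:
        return W, P, T, c, np.zeros(X.shape[1])
    # b = W (P'W)^-1 c
    b = W @ np.linalg.solve(P.T @ W, c)
    return W, P, T, c, b


class PLSRegression1:
    """PLS1 model of a clinical factor y on a metabolite block X.

    Parameters
    ----------
    X
        samples x features DataFrame (e.g. a completed fold-change matrix or
        a targeted block); must be column-complete.
    y
        per-sample clinical factor aligned with X rows.
    n_components
        Fixed component count; ``None`` selects argmax of CV Q2 over 1..5.
    groups
        Optional per-sample stratification labels for CV folds (treatment
        arms when modelling the full cohort).
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: pd.Series,
        n_components: int | None = 2,
        cv_folds: int = 7,
        seed: int = 0,
        groups: pd.Series | None = None,
    ) -> None:
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(X) < 5:
            raise ValueError("need at least 5 samples")
        yv = np.asarray(y, dtype=float)
        if np.std(yv) == 0:
            raise ValueError("factor has zero variance")
        if np.isnan(X.to_numpy()).any():
            raise ValueError("X must be column-complete; impute first")
        self.X, self.y = X, pd.Series(yv, index=X.index, name=getattr(y, "name", "y"))
        self.cv_folds = cv_folds
        self.seed = seed
        self.groups = groups
        if n_components is None:
            n_components = select_n_components(X.to_numpy(), yv, folds=cv_folds,
                                               seed=seed, groups=groups)
        self.n_components = int(min(n_components, len(X) - 1, X.shape[1]))

    def fit(self) -> "PLSResults":
        Xc, yc, xm, xs, ym = _center_scale(self.X.to_numpy(), self.y.to_numpy())
        W, P, T, c, b = _nipals_pls1(Xc, yc, self.n_components)
        yhat = T @ c
        tss = float(yc @ yc)
        r2y = 1.0 - float((yc - yhat) @ (yc - yhat)) / tss
        q2 = q2y_cv(self.X.to_numpy(), self.y.to_numpy(), W.shape[1],
                    folds=self.cv_folds, seed=self.seed, groups=self.groups)
        comp = [f"C{a + 1}" for a in range(W.shape[1])]
        return PLSResults(
            model=self,
            weights=pd.DataFrame(W, index=self.X.columns, columns=comp),
            x_loadings=pd.DataFrame(P, index=self.X.columns, columns=comp),
            scores=pd.DataFrame(T, index=self.X.index, columns=comp),
            y_loadings=pd.Series(c, index=comp),
            coef=pd.Series(b, index=self.X.columns),
            r2y=r2y,
            q2y=q2,
            preprocessing="center_uv",
        )


@dataclass
class PLSResults:
    """Fitted PLS1 model: weights, scores, loadings, R2Y and CV Q2."""

    model: PLSRegression1
    weights: pd.DataFrame
    x_loadings: pd.DataFrame
    scores: pd.DataFrame
    y_loadings: pd.Series
    coef: pd.Series
    r2y: float
    q2y: float
    preprocessing: str

    def predict(self, Xnew: pd.DataFrame | np.ndarray) -> np.ndarray:
        Xc, _, xm, xs, ym = _center_scale(self.model.X.to_numpy(),
                                          self.model.y.to_numpy())
        Xn = np.asarray(Xnew, dtype=float)
        return (Xn - xm) / xs @ self.coef.to_numpy() + ym

    def permutation_test(self, B: int = 1000, seed: int = 0,
                         q2_threshold: float = 0.15,
                         perm_p_threshold: float = 0.01) -> "PermutationReport":
        """Permutation validity test against B mismatched-Y null models.

        Each permutation reruns the full pipeline (fit and cross-validated
        Q2). perm_p = (1 + #{null Q2 >= true Q2}) / (B + 1); the model is
        valid iff Q2 exceeds ``q2_threshold`` and perm_p is below
        ``perm_p_threshold``. First-component weights of the null models
        feed the per-feature empirical selection p-values.
        """
        if B <= 0:
            raise ValueError("B must be positive")
        m = self.model
        rng = np.random.default_rng(seed)
        Xv, yv = m.X.to_numpy(), m.y.to_numpy()
        k = self.weights.shape[1]
        # Component-1 weights are compared on the covariance scale (X~'y~,
        # i.e. before per-model unit normalisation): a unit-normalised true
        # weight vector is shrunk feature-wise whenever many features carry
        # signal, which would destroy the calibration of the per-feature
        # null comparison.
        Xc_true, yc_true, *_ = _center_scale(Xv, yv)
        null_q2 = np.empty(B)
        null_w1 = np.empty((B, Xv.shape[1]))
        for bi in range(B):
            yp = rng.permutation(yv)
            null_w1[bi] = Xc_true.T @ (yp - yp.mean())
            null_q2[bi] = q2y_cv(Xv, yp, k, folds=m.cv_folds, seed=m.seed,
                                 groups=m.groups)
        perm_p = (1.0 + float((null_q2 >= self.q2y).sum())) / (B + 1.0)
        valid = (self.q2y > q2_threshold) and (perm_p < perm_p_threshold)
        w_true = Xc_true.T @ yc_true
        emp_p = (1.0 + (np.abs(null_w1) >= np.abs(w_true)[None, :]).sum(axis=0)) / (B + 1.0)
        exceed = np.where(w_true >= 0,
                          (null_w1 >= w_true[None, :]).sum(axis=0),
                          (null_w1 <= w_true[None, :]).sum(axis=0))
        emp_p_signed = (1.0 + exceed) / (B + 1.0)
        feature_table = pd.DataFrame({
            "w": w_true,
            "null_w_abs_q95": np.quantile(np.abs(null_w1), 0.95, axis=0),
            "empirical_p": emp_p,
            "empirical_p_signed": emp_p_signed,
            "selected": valid & (emp_p < 0.05),
        }, index=m.X.columns)
        return PermutationReport(
            B=B, q2y=self.q2y, r2y=self.r2y, null_q2y=null_q2, perm_p=perm_p,
            valid=bool(valid), q2_threshold=q2_threshold,
            perm_p_threshold=perm_p_threshold, feature_table=feature_table,
        )

    def summary(self) -> str:
        return (
            f"PLS1 ({self.weights.shape[1]} component(s), {self.preprocessing}, "
            f"{self.model.cv_folds}-fold CV)\n"
            f"  n = {len(self.scores)}, p = {len(self.coef)}, "
            f"factor = {self.model.y.name}\n"
            f"  R2Y = {self.r2y:.4f}   Q2Y = {self.q2y:.4f}"
        )


@dataclass
class PermutationReport:
    """Outcome of the mismatched-Y permutation validity test."""

    B: int
    q2y: float
    r2y: float
    null_q2y: np.ndarray
    perm_p: float
    valid: bool
    q2_threshold: float
    perm_p_threshold: float
    feature_table: pd.DataFrame

    def select_features(self, alpha: float = 0.05, signed: bool = False) -> list[str]:
        """Features whose first-component weight beats the permutation null.

        Selection is only reported for valid models (empty list otherwise).
        ``signed=True`` uses the one-sided signed comparison instead of
        |weight|.
        """
        if not self.valid:
            return []
        t = self.feature_table
        col = "empirical_p_signed" if signed else "empirical_p"
        return t.index[t[col] < alpha].tolist()

    def summary(self) -> str:
        nsel = int(self.feature_table["selected"].sum()) if self.valid else 0
        return (
            f"Permutation validity (B = {self.B}): Q2Y = {self.q2y:.4f} "
            f"(threshold {self.q2_threshold}), perm p = {self.perm_p:.4g} "
            f"(threshold {self.perm_p_threshold}) -> "
            f"{'VALID' if self.valid else 'not valid'}; "
            f"{nsel} feature(s) selected at empirical p < 0.05"
        )


def _fold_assignment(n: int, folds: int, seed: int,
                     groups: np.ndarray | None) -> np.ndarray:
    """Deterministic (seeded) fold labels, stratified by group when given."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=int)
    if groups is None:
        perm = rng.permutation(n)
        assign[perm] = np.arange(n) % folds
    else:
        groups = np.asarray(groups)
        for g in pd.unique(groups):
            idx = np.flatnonzero(groups == g)
            perm = rng.permutation(idx)
            assign[perm] = np.arange(len(idx)) % folds
    return assign


def q2y_cv(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    folds: int = 7,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> float:
    """Cross-validated Q2 = 1 - PRESS/TSS.

    Centering/scaling and the PLS fit are redone on each training fold;
    TSS measures test deviations from the training-fold mean, so a model no
    better than the mean scores Q2 <= 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    assign = _fold_assignment(n, folds, seed, groups)
    press = 0.0
    tss = 0.0
    for f in range(folds):
        test = assign == f
        train = ~test
        if test.sum() < 1:
            raise ValueError(f"fold {f} has no test sample")
        k = min(n_components, int(train.sum()) - 1, X.shape[1])
        Xc, yc, xm, xs, ym = _center_scale(X[train], y[train])
        _, _, _, _, b = _nipals_pls1(Xc, yc, k)
        pred = (X[test] - xm) / xs @ b + ym
        press += float(((y[test] - pred) ** 2).sum())
        tss += float(((y[test] - ym) ** 2).sum())
    return 1.0 - press / tss


def select_n_components(
    X: np.ndarray,
    y: np.ndarray,
    kmax: int = 5,
    folds: int = 7,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> int:
    """Component count maximising cross-validated Q2 over 1..kmax."""
    kmax = int(min(kmax, len(y) - 2, np.asarray(X).shape[1]))
    best_k, best_q2 = 1, -np.inf
    for k in range(1, kmax + 1):
        q2 = q2y_cv(X, y, k, folds=folds, seed=seed, groups=groups)
        if q2 > best_q2:
            best_k, best_q2 = k, q2
    return best_k
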