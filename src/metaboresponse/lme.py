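"""Per-feature linear mixed-effects interaction modelling with FDR control.

The model for each feature is

    log(intensity) ~ timepoint * group + (1 | subject)

i.e. fixed effects for timepoint (baseline / week4), treatment group
(reference SAL) and their interaction, plus a subject-specific random
intercept. The treatment effect of interest is the timepoint-by-group
interaction; pairwise intervention comparisons are Wald t contrasts between
interaction coefficients, with Benjamini-Hochberg FDR control applied per
contrast family across features.

Fitting is REML. The variance-ratio profile lambda = sigma2_subject /
sigma2_resid reduces the problem to a one-dimensional bounded optimisation
(Brent), evaluated in an eigenbasis of the subject-grouping structure in
which V(lambda) is diagonal. For the common special case of complete
balanced pairs (every subject measured at both timepoints) the REML
estimates have a closed form via the orthogonal within-subject difference
and subject-mean strata; this fast path is vectorised across features and
agrees with the iterative path to numerical precision.

Modelling is on the natural-log scale (sigma estimates are ln-scale);
reported effect estimates carry a log2-converted column for display parity
with fold-change analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .data import GROUPS, FeatureMatrix, StudyError
from .foldchange import FoldChangeMatrix

__all__ = [
    "bh_fdr",
    "LMEFit",
    "InteractionMixedLM",
    "InteractionMixedLMResults",
    "power_simulation",
]

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j over the m non-missing p-values,
    capped at 1. NaN entries propagate NaN and do not count towards m.
    Values outside [0, 1] raise.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    qv = np.empty(m)
    qv[order] = q
    out[mask] = qv
    return out


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _build_design(
    samples: pd.DataFrame,
    factor: pd.Series | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray, list[str], str]:
    """Treatment-coded design for timepoint * group (+ optional 3-way factor).

    Returns (X, column names, subject integer codes, group order, ref group).
    The reference level is SAL when present. With ``factor`` (a per-subject
    clinical delta), four timepoint:group:factor columns are appended — one
    per group level including the reference.
    """
    present = [g for g in GROUPS if g in set(samples["group"])]
    if len(present) < 2:
        raise StudyError("need at least 2 treatment groups")
    ref = "SAL" if "SAL" in present else present[0]
    others = [g for g in present if g != ref]

    t = (samples["timepoint"] == "week4").to_numpy(dtype=float)
    cols = [np.ones(len(samples)), t]
    names = ["Intercept", "time"]
    for g in others:
        gi = (samples["group"] == g).to_numpy(dtype=float)
        cols.append(gi)
        names.append(f"group[{g}]")
    for g in others:
        gi = (samples["group"] == g).to_numpy(dtype=float)
        cols.append(t * gi)
        names.append(f"time:group[{g}]")
    if factor is not None:
        fac = samples["subject_id"].map(factor)
        if fac.isna().any():
            missing = sorted(samples.loc[fac.isna(), "subject_id"].unique())
            raise StudyError(f"clinical factor missing for subjects {missing}")
        fv = fac.to_numpy(dtype=float)
        for g in present:
            gi = (samples["group"] == g).to_numpy(dtype=float)
            cols.append(t * gi * fv)
            names.append(f"time:group[{g}]:factor")
    X = np.column_stack(cols)
    subj_codes, _ = pd.factorize(samples["subject_id"], sort=False)
    return X, names, subj_codes, present, ref


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop rank-deficient columns via pivoted QR; keeps leading structure."""
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"dropping collinear design column(s): {dropped}")
    return X[:, keep], [names[j] for j in keep], dropped


# ---------------------------------------------------------------------------
# REML engine
# ---------------------------------------------------------------------------

def _helmert_basis(n: int) -> np.ndarray:
    """Orthonormal n x n basis whose first vector is 1/sqrt(n)."""
    A = np.zeros((n, n))
    A[:, 0] = 1.0
    if n > 1:
        A[:, 1:] = np.eye(n)[:, : n - 1]
    Q, _ = np.linalg.qr(A)
    if Q[0, 0] < 0:
        Q = -Q
    return Q


class _REMLEngine:
    """Profiled-REML machinery for one design shared across features.

    Rotates the model into an orthonormal basis aligned with the subject
    grouping, where V(lambda) = I + lambda * Z Z' becomes diagonal with
    entries 1 + lambda * n_i. Each feature then costs one scalar Brent
    search over log-lambda with O(n p^2) work per criterion evaluation.
    """

    def __init__(self, X: np.ndarray, subj_codes: np.ndarray) -> None:
        n = X.shape[0]
        order = np.argsort(subj_codes, kind="stable")
        self.order = order
        sizes = np.bincount(subj_codes)
        basis_cache: dict[int, np.ndarray] = {}
        blocks, dvals = [], []
        for ni in sizes:
            if ni == 0:
                continue
            if ni not in basis_cache:
                basis_cache[ni] = _helmert_basis(int(ni))
            blocks.append(basis_cache[ni])
            dvals.extend([float(ni)] + [0.0] * (int(ni) - 1))
        U = linalg.block_diag(*blocks)
        self.d = np.asarray(dvals)
        self.Ut_rows = U.T  # acts on subject-sorted rows
        self.X = X
        self.Xt = self.Ut_rows @ X[order]
        self.n, self.p = X.shape
        self.n_subjects = int((sizes > 0).sum())

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return self.Ut_rows @ y[self.order]

    def _wls(self, lam: float, yt: np.ndarray):
        w = 1.0 / (1.0 + lam * self.d)
        Xw = self.Xt * w[:, None]
        A = Xw.T @ self.Xt
        beta = np.linalg.solve(A, Xw.T @ yt)
        resid = yt - self.Xt @ beta
        rss = float(np.dot(w * resid, resid))
        return w, A, beta, rss

    def _crit(self, lam: float, yt: np.ndarray) -> float:
        # -2 * restricted loglik, dropping lambda-free constants
        _, A, _, rss = self._wls(lam, yt)
        npf = self.n - self.p
        sign, logdet = np.linalg.slogdet(A)
        if sign <= 0 or rss <= 0:
            return np.inf
        return npf * np.log(rss) + float(np.sum(np.log1p(lam * self.d))) + logdet

    def reml_loglik(self, lam: float, yt: np.ndarray) -> float:
        _, A, _, rss = self._wls(lam, yt)
        npf = self.n - self.p
        sig2 = rss / npf
        _, logdet = np.linalg.slogdet(A)
        return -0.5 * (
            npf * (np.log(2 * np.pi * sig2) + 1.0)
            + float(np.sum(np.log1p(lam * self.d)))
            + logdet
        )

    def _crit_grad(self, lam: float, yt: np.ndarray) -> float:
        """d/d(lambda) of the -2 restricted loglik (envelope theorem in beta)."""
        w, A, beta, rss = self._wls(lam, yt)
        resid = yt - self.Xt @ beta
        drss = -float(np.sum(self.d * (w * resid) ** 2))
        Ap = (self.Xt * (self.d * w * w)[:, None]).T @ self.Xt
        tr = float(np.trace(np.linalg.solve(A, Ap)))
        return (self.n - self.p) * drss / rss + float(np.sum(self.d * w)) - tr

    def fit_feature(self, y: np.ndarray):
        """Maximise the restricted likelihood over lambda >= 0 for one response."""
        yt = self.transform_y(y)
        res = optimize.minimize_scalar(
            lambda th: self._crit(np.exp(th), yt),
            bounds=(-16.0, 16.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        lam = float(np.exp(res.x))
        # The criterion is flat to ~sqrt(eps) near the optimum; polish lambda
        # to machine precision via a sign change of the analytic gradient.
        lo, hi = lam / 1.5, lam * 1.5
        try:
            glo, ghi = self._crit_grad(lo, yt), self._crit_grad(hi, yt)
            if np.isfinite(glo) and np.isfinite(ghi) and glo < 0 < ghi:
                lam = float(optimize.brentq(
                    lambda l: self._crit_grad(l, yt), lo, hi, xtol=1e-14,
                    rtol=1e-14))
        except (ValueError, np.linalg.LinAlgError):
            pass
        best = self._crit(lam, yt)
        at_zero = self._crit(0.0, yt)
        boundary = False
        if at_zero <= best:
            lam, best = 0.0, at_zero
            boundary = True
        converged = bool(np.isfinite(best))
        _, A, beta, rss = self._wls(lam, yt)
        sig2e = rss / (self.n - self.p)
        vcov = sig2e * np.linalg.inv(A)
        loglik = self.reml_loglik(lam, yt)
        return beta, vcov, lam * sig2e, sig2e, loglik, converged, boundary


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------

@dataclass
class LMEFit:
    """REML fit of the interaction model for a single feature."""

    feature_id: str
    params: pd.Series  # ln-scale fixed effects
    vcov: pd.DataFrame
    sigma2_subject: float
    sigma2_resid: float
    reml_loglik: float
    converged: bool
    boundary: bool
    df_containment: int
    groups: list[str]
    ref: str

    def contrast(self, a: str, b: str) -> tuple[float, float]:
        """Interaction contrast a - b (ln scale) and its standard error."""
        c = np.zeros(len(self.params))
        for g, sgn in ((a, 1.0), (b, -1.0)):
            if g == self.ref:
                continue
            name = f"time:group[{g}]"
            if name not in self.params.index:
                raise StudyError(f"group {g!r} absent from fitted model")
            c[self.params.index.get_loc(name)] = sgn
        est = float(c @ self.params.to_numpy())
        se = float(np.sqrt(c @ self.vcov.to_numpy() @ c))
        return est, se


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------

class InteractionMixedLM:
    """Batch per-feature mixed model over a feature matrix.

    Parameters
    ----------
    fm
        Feature matrix restricted to one biofluid (pass ``biofluid=`` to
        subset). Intensities are modelled on the natural-log scale.
    adjust_factor
        Optional per-subject clinical delta; adds timepoint:group:factor
        three-way columns (confounder-adjusted variant).
    """

    def __init__(
        self,
        fm: FeatureMatrix,
        biofluid: str | None = None,
        platforms: list[str] | None = None,
        adjust_factor: pd.Series | None = None,
    ) -> None:
        if biofluid is not None or platforms is not None:
            fm = fm.subset(biofluid=biofluid, platforms=platforms)
        fluids = set(fm.samples["biofluid"])
        if len(fluids) > 1:
            raise StudyError(f"fit one biofluid at a time, got {sorted(fluids)}")
        self.fm = fm
        self.adjust_factor = adjust_factor
        samples = fm.samples
        if adjust_factor is not None:
            have = samples["subject_id"].isin(adjust_factor.dropna().index)
            if not have.all():
                dropped = sorted(samples.loc[~have, "subject_id"].unique())
                warnings.warn(f"dropping subjects without clinical factor: {dropped}")
                samples = samples[have]
                self.fm = FeatureMatrix(samples.copy(), fm.features.copy(),
                                        fm.values.loc[samples.index].copy())
        X, names, subj, present, ref = _build_design(self.fm.samples, adjust_factor)
        X, names, self.dropped_columns = _drop_collinear(X, names)
        self._X, self._names, self._subj = X, names, subj
        self.groups_present, self.ref = present, ref
        counts = self.fm.samples.drop_duplicates("subject_id")["group"].value_counts()
        self.n_per_group = {g: int(counts.get(g, 0)) for g in present}
        self.n_subjects = int(counts.sum())
        self.df_containment = self.n_subjects - len(present)

    # -- balance detection ------------------------------------------------
    def _is_balanced(self) -> bool:
        if self.adjust_factor is not None:
            return False
        s = self.fm.samples
        per = s.groupby("subject_id")["timepoint"].agg(["count", "nunique"])
        if not ((per["count"] == 2) & (per["nunique"] == 2)).all():
            return False
        return not self.fm.values.isna().any().any()

    def fit(self, method: str = "auto") -> "InteractionMixedLMResults":
        """Fit every feature; method is "auto", "closed_form" or "profile".

        "auto" uses the closed-form balanced-pair path when the design is
        complete and unadjusted, falling back to the profiled iterative
        path otherwise (and per feature when the balanced variance estimate
        hits the sigma2_subject = 0 boundary).
        """
        if method not in ("auto", "closed_form", "profile"):
            raise ValueError(method)
        balanced = self._is_balanced()
        if method == "closed_form" and not balanced:
            raise StudyError("closed-form path needs complete balanced pairs")
        if method in ("auto", "closed_form") and balanced:
            return self._fit_closed_form()
        return self._fit_profile()

    # -- iterative profiled REML -----------------------------------------
    def _fit_profile(self) -> "InteractionMixedLMResults":
        Y = self.fm.log_values(base=np.e)
        feats = Y.columns
        engines: dict[bytes, tuple[_REMLEngine, np.ndarray]] = {}
        p = len(self._names)
        F = len(feats)
        params = np.full((F, p), np.nan)
        vcov = np.full((F, p, p), np.nan)
        s2b = np.full(F, np.nan)
        s2e = np.full(F, np.nan)
        ll = np.full(F, np.nan)
        conv = np.zeros(F, dtype=bool)
        bound = np.zeros(F, dtype=bool)
        arr = Y.to_numpy()
        for j in range(F):
            y = arr[:, j]
            mask = ~np.isnan(y)
            key = mask.tobytes()
            if key not in engines:
                engines[key] = (_REMLEngine(self._X[mask], self._subj[mask]), mask)
            eng, m = engines[key]
            try:
                beta, V, sb, se_, lg, ok, bd = eng.fit_feature(y[m])
            except np.linalg.LinAlgError:
                continue
            params[j], vcov[j], s2b[j], s2e[j], ll[j] = beta, V, sb, se_, lg
            conv[j], bound[j] = ok, bd
        return InteractionMixedLMResults(
            self, feats, self._names, params, vcov, s2b, s2e, ll, conv, bound
        )

    # -- closed-form balanced pairs --------------------------------------
    def _fit_closed_form(self) -> "InteractionMixedLMResults":
        fmv = self.fm.log_values(base=np.e)
        s = self.fm.samples.reset_index()
        base = s[s["timepoint"] == "baseline"].set_index("subject_id")
        week4 = s[s["timepoint"] == "week4"].set_index("subject_id")
        subjects = base.index
        Yb = fmv.loc[base["sample_id"]].to_numpy()
        Yw = fmv.loc[week4.loc[subjects, "sample_id"]].to_numpy()
        D = Yw - Yb  # within-subject differences, Var = 2 sigma2_e
        M = 0.5 * (Yw + Yb)  # subject means, Var = sigma2_b + sigma2_e / 2
        groups = base.loc[subjects, "group"]
        present, ref = self.groups_present, self.ref
        G = len(present)
        N = len(subjects)
        dfres = N - G
        ng = np.array([self.n_per_group[g] for g in present], dtype=float)

        gidx = {g: i for i, g in enumerate(present)}
        gcodes = groups.map(gidx).to_numpy()
        dbar = np.zeros((G, D.shape[1]))
        mbar = np.zeros((G, D.shape[1]))
        ssd = np.zeros(D.shape[1])
        ssm = np.zeros(D.shape[1])
        for i in range(G):
            rows = gcodes == i
            dbar[i] = D[rows].mean(axis=0)
            mbar[i] = M[rows].mean(axis=0)
            ssd += ((D[rows] - dbar[i]) ** 2).sum(axis=0)
            ssm += ((M[rows] - mbar[i]) ** 2).sum(axis=0)
        sig2e = ssd / (2.0 * dfres)
        tau = ssm / dfres  # sigma2_b + sigma2_e / 2
        sig2b = tau - sig2e / 2.0

        # boundary features: REML maximum at sigma2_subject = 0
        bad = sig2b < 0

        # beta = L [mbar; dbar]; independent strata with Var(mbar_g) = tau / n_g,
        # Var(dbar_g) = 2 sigma2_e / n_g
        names = self._names
        p = len(names)
        L = np.zeros((p, 2 * G))
        iref = gidx[ref]
        L[names.index("Intercept"), iref] = 1.0
        L[names.index("Intercept"), G + iref] = -0.5
        L[names.index("time"), G + iref] = 1.0
        for g in present:
            if g == ref:
                continue
            i = gidx[g]
            L[names.index(f"group[{g}]"), i] = 1.0
            L[names.index(f"group[{g}]"), iref] = -1.0
            L[names.index(f"group[{g}]"), G + i] = -0.5
            L[names.index(f"group[{g}]"), G + iref] = 0.5
            L[names.index(f"time:group[{g}]"), G + i] = 1.0
            L[names.index(f"time:group[{g}]"), G + iref] = -1.0

        stat = np.vstack([mbar, dbar])  # (2G, F)
        params = (L @ stat).T  # (F, p)
        Fn = params.shape[0]
        # vcov_f = L diag([tau_f/n_g, 2 sig2e_f/n_g]) L'
        inv_n = 1.0 / ng
        Lm, Ld = L[:, :G], L[:, G:]
        Am = np.einsum("pg,qg,g->pq", Lm, Lm, inv_n)
        Ad = np.einsum("pg,qg,g->pq", Ld, Ld, inv_n)
        vcov = tau[:, None, None] * Am[None] + (2.0 * sig2e)[:, None, None] * Ad[None]

        ll = self._loglik_at(params, sig2b, sig2e, fmv)
        conv = np.ones(Fn, dtype=bool)
        res = InteractionMixedLMResults(
            self, fmv.columns, names, params, vcov,
            np.maximum(sig2b, 0.0), sig2e, ll, conv, bad.copy(),
        )
        if bad.any():
            res._refit_boundary(np.flatnonzero(bad), fmv)
        return res

    def _loglik_at(self, params, sig2b, sig2e, fmv) -> np.ndarray:
        """Restricted loglik evaluated at given variance components (vectorised)."""
        eng = _REMLEngine(self._X, self._subj)
        Yt = eng.transform_y(fmv.to_numpy())
        lam = np.where(sig2e > 0, np.maximum(sig2b, 0.0) / np.where(sig2e > 0, sig2e, 1.0), 0.0)
        npf = eng.n - eng.p
        F = params.shape[0]
        ll = np.full(F, np.nan)
        W = 1.0 / (1.0 + lam[None, :] * eng.d[:, None])  # n x F
        resid = Yt - eng.Xt @ params.T
        rss = (W * resid ** 2).sum(axis=0)
        logv = np.log1p(lam[None, :] * eng.d[:, None]).sum(axis=0)
        for f in range(F):
            A = (eng.Xt * W[:, f : f + 1]).T @ eng.Xt
            _, logdet = np.linalg.slogdet(A)
            sig2 = rss[f] / npf
            ll[f] = -0.5 * (npf * (np.log(2 * np.pi * sig2) + 1.0) + logv[f] + logdet)
        return ll


@dataclass
class InteractionMixedLMResults:
    """Batch REML results: per-feature coefficients, vcov and diagnostics."""

    model: InteractionMixedLM
    feature_ids: pd.Index
    param_names: list[str]
    params: np.ndarray  # F x p, ln scale
    vcov: np.ndarray  # F x p x p
    sigma2_subject: np.ndarray
    sigma2_resid: np.ndarray
    reml_loglik: np.ndarray
    converged: np.ndarray
    boundary: np.ndarray

    def _refit_boundary(self, idx: np.ndarray, fmv: pd.DataFrame) -> None:
        """Re-fit features whose balanced estimate fell below sigma2_b = 0."""
        eng = _REMLEngine(self.model._X, self.model._subj)
        arr = fmv.to_numpy()
        for j in idx:
            beta, V, sb, se_, lg, ok, bd = eng.fit_feature(arr[:, j])
            self.params[j], self.vcov[j] = beta, V
            self.sigma2_subject[j], self.sigma2_resid[j] = sb, se_
            self.reml_loglik[j], self.converged[j], self.boundary[j] = lg, ok, True

    # -- accessors --------------------------------------------------------
    def fit_for(self, feature_id: str) -> LMEFit:
        j = self.feature_ids.get_loc(feature_id)
        return LMEFit(
            feature_id,
            pd.Series(self.params[j], index=self.param_names),
            pd.DataFrame(self.vcov[j], index=self.param_names, columns=self.param_names),
            float(self.sigma2_subject[j]),
            float(self.sigma2_resid[j]),
            float(self.reml_loglik[j]),
            bool(self.converged[j]),
            bool(self.boundary[j]),
            self.model.df_containment,
            self.model.groups_present,
            self.model.ref,
        )

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.params, index=self.feature_ids, columns=self.param_names)

    # -- contrasts --------------------------------------------------------
    def contrasts(self, pairs: str | list[tuple[str, str]] = "vs_sal") -> pd.DataFrame:
        """Wald interaction contrasts for each feature and group pair.

        ``pairs`` is "vs_sal" (the three active-vs-control comparisons),
        "all_pairs" (all six), or an explicit list of (a, b) tuples.
        Returns a long table with ln- and log2-scale estimates, se, t,
        containment df, p and BH q computed within each pair family.
        """
        present, ref = self.model.groups_present, self.model.ref
        if pairs == "vs_sal":
            plist = [(g, ref) for g in present if g != ref]
        elif pairs == "all_pairs":
            # later-listed group first, so every pair reads active_vs_control
            plist = [(present[j], present[i])
                     for i in range(len(present)) for j in range(i + 1, len(present))]
        else:
            plist = list(pairs)
        for a, b in plist:
            for g in (a, b):
                if g not in present:
                    raise StudyError(f"group {g!r} absent from fitted model")
        names = self.param_names
        p = len(names)
        df = self.model.df_containment
        frames = []
        for a, b in plist:
            c = np.zeros(p)
            if a != ref:
                c[names.index(f"time:group[{a}]")] = 1.0
            if b != ref:
                c[names.index(f"time:group[{b}]")] = -1.0
            est = self.params @ c
            var = np.einsum("i,fij,j->f", c, self.vcov, c)
            se = np.sqrt(var)
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = est / se
            pval = 2.0 * stats.t.sf(np.abs(tstat), df)
            pval = np.where(self.converged, pval, np.nan)
            frames.append(pd.DataFrame({
                "feature_id": self.feature_ids,
                "pair": f"{a}_vs_{b}",
                "estimate": est,
                "estimate_log2": est / LN2,
                "se": se,
                "df": df,
                "t": tstat,
                "p": pval,
                "q": bh_fdr(pval),
            }))
        return pd.concat(frames, ignore_index=True)

    def percent_significant(self, alpha: float = 0.05,
                            pairs: str = "vs_sal") -> pd.Series:
        """Percentage of features with q < alpha, per group pair."""
        con = self.contrasts(pairs)
        return con.groupby("pair").apply(
            lambda t: 100.0 * float((t["q"] < alpha).sum()) / len(t),
            include_groups=False,
        )

    def summary(self, alpha: float = 0.05) -> str:
        pct = self.percent_significant(alpha)
        lines = [
            "Per-feature mixed model: log(intensity) ~ timepoint * group + (1|subject)",
            f"  features: {len(self.feature_ids)}   subjects: {self.model.n_subjects}"
            f"   groups: {self.model.groups_present} (ref {self.model.ref})",
            f"  inference: Wald t, containment df = {self.model.df_containment};"
            f" BH-FDR per contrast family",
            f"  non-converged: {int((~self.converged).sum())}"
            f"   boundary sigma2_subject=0: {int(self.boundary.sum())}",
            f"  % features with q < {alpha:g}:",
        ]
        for pair, v in pct.items():
            lines.append(f"    {pair:>14}: {v:5.1f}%")
        return "\n".join(lines)

    # -- confounder sensitivity ------------------------------------------
    def confounder_sensitive(
        self, adjusted: "InteractionMixedLMResults", alpha: float = 0.05
    ) -> pd.DataFrame:
        """Features losing vs-SAL significance once the clinical factor enters."""
        un = self.contrasts("vs_sal").set_index(["feature_id", "pair"])
        ad = adjusted.contrasts("vs_sal").set_index(["feature_id", "pair"])
        joined = un[["q"]].join(ad[["q"]], lsuffix="_unadjusted", rsuffix="_adjusted")
        joined["confounder_sensitive"] = (
            (joined["q_unadjusted"] < alpha) & ~(joined["q_adjusted"] < alpha)
        )
        return joined.reset_index()


# ---------------------------------------------------------------------------
# power simulation
# ---------------------------------------------------------------------------

def power_simulation(
    fc: FoldChangeMatrix,
    target_group: str = "GOP",
    target_n: int = 21,
    B: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    control: str = "SAL",
) -> dict:
    """Bootstrap power analysis for enlarging one arm.

    Resamples ``target_group`` subjects with replacement to ``target_n``
    (the control arm held fixed), reruns the two-group interaction test per
    feature on the per-subject paired log fold changes with BH-FDR, and
    reports the distribution of the count of q < alpha features.

    The paired-difference formulation is the balanced-pair closed form of
    the full mixed model restricted to two groups, so counts match a full
    refit.
    """
    if B < 10:
        warnings.warn(f"B={B} bootstrap replicates is very small")
    rng = np.random.default_rng(seed)
    tgt = fc.values[fc.groups == target_group].to_numpy()
    ctl = fc.values[fc.groups == control].to_numpy()
    n_t, n_c = len(tgt), len(ctl)
    if n_t == 0 or n_c == 0:
        raise StudyError("target or control group empty in fold-change matrix")
    if target_n < n_t:
        raise StudyError(f"target_n={target_n} below current size {n_t}")
    counts = np.empty(B, dtype=int)
    dfres = target_n + n_c - 2
    for b in range(B):
        idx = rng.integers(0, n_t, size=target_n)
        Dt = tgt[idx]
        est = Dt.mean(axis=0) - ctl.mean(axis=0)
        ss = ((Dt - Dt.mean(axis=0)) ** 2).sum(axis=0) + ((ctl - ctl.mean(axis=0)) ** 2).sum(axis=0)
        var_d = ss / dfres
        se = np.sqrt(var_d * (1.0 / target_n + 1.0 / n_c))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est / se
        p = 2.0 * stats.t.sf(np.abs(t), dfres)
        q = bh_fdr(p)
        counts[b] = int((q < alpha).sum())
    return {
        "counts": counts,
        "mean": float(counts.mean()),
        "ci95": (float(np.percentile(counts, 2.5)), float(np.percentile(counts, 97.5))),
        "target_n": target_n,
        "B": B,
    }
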