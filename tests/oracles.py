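"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's fitting machinery: dense-matrix GLS
with a grid/golden search over the variance ratio for the random-intercept
model, and the analytic cross-covariance direction for PLS.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def dense_reml_loglik(y, X, subj_codes, lam):
    """Restricted loglik of a random-intercept model via dense V matrices."""
    n, p = X.shape
    Z = np.zeros((n, subj_codes.max() + 1))
    Z[np.arange(n), subj_codes] = 1.0
    V = np.eye(n) + lam * Z @ Z.T
    Vinv = np.linalg.inv(V)
    A = X.T @ Vinv @ X
    beta = np.linalg.solve(A, X.T @ Vinv @ y)
    r = y - X @ beta
    rss = float(r @ Vinv @ r)
    sig2 = rss / (n - p)
    _, ldV = np.linalg.slogdet(V)
    _, ldA = np.linalg.slogdet(A)
    ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sig2) + 1.0) + ldV + ldA)
    return ll, beta, sig2


def gls_grid_reml(y, X, subj_codes):
    """Brute-force REML: coarse lambda grid then golden-section refinement.

    Returns (beta, sigma2_subject, sigma2_resid, lam, loglik).
    """
    y = np.asarray(y, dtype=float)
    subj_codes = np.asarray(subj_codes)
    grid = np.concatenate([[0.0], np.logspace(-8, 5, 261)])
    lls = np.array([dense_reml_loglik(y, X, subj_codes, l)[0] for l in grid])
    i = int(np.argmax(lls))
    if i == 0:
        lam = 0.0
    else:
        lo = np.log(grid[max(i - 1, 1)])
        hi = np.log(grid[min(i + 1, len(grid) - 1)])
        res = optimize.minimize_scalar(
            lambda t: -dense_reml_loglik(y, X, subj_codes, np.exp(t))[0],
            bracket=None, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        lam = float(np.exp(res.x))
        if dense_reml_loglik(y, X, subj_codes, 0.0)[0] >= \
                dense_reml_loglik(y, X, subj_codes, lam)[0]:
            lam = 0.0
    ll, beta, sig2 = dense_reml_loglik(y, X, subj_codes, lam)
    return beta, lam * sig2, sig2, lam, ll


def pls1_first_weight(X, y):
    """Analytic first-component PLS weight direction: X~' y~ (centered/UV)."""
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    Xc = Xc / sd
    yc = y - y.mean()
    v = Xc.T @ yc
    return v / np.linalg.norm(v)


def bh_stepup_reference(p):
    """Literal step-up definition q_i = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_idx in range(m):
        j = np.arange(rank_idx, m)
        q[order[rank_idx]] = min(1.0, np.min(p[order[j]] * m / (j + 1)))
    return q
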