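"""Cross-intervention similarity: mean fold changes, congruence, categories,
and per-feature clinical correlations.

Two interventions can alter overlapping feature sets in correlated
directions even when the per-feature significance calls differ; these
summaries quantify that. Mean log2 fold changes per arm are correlated
between intervention pairs (Pearson), features are categorised as shared /
uniquely significant per the vs-control mixed-model q-values, and
per-feature fold changes are correlated with clinical deltas (unadjusted p
for display masks, optional BH column).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ClinicalTable, StudyError
from .foldchange import FoldChangeMatrix
from .lme import bh_fdr

__all__ = [
    "mean_fold_changes",
    "CongruenceReport",
    "pairwise_congruence",
    "clinical_correlations",
]

CATEGORIES = ("shared", "unique_VLCD", "unique_RYGB", "unique_GOP", "nonsignificant")


def mean_fold_changes(fc: FoldChangeMatrix) -> pd.DataFrame:
    """Per-feature, per-arm mean log2 fold change with t-based 95% CI.

    Returns a long table (feature_id, group, mean, sd, n, ci_low, ci_high).
    Arms with fewer than 2 subjects raise.
    """
    rows = []
    for g in fc.groups.unique():
        block = fc.values[fc.groups == g]
        n = len(block)
        if n < 2:
            raise StudyError(f"group {g!r} has fewer than 2 subjects")
        m = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        rows.append(pd.DataFrame({
            "feature_id": fc.features,
            "group": g,
            "mean": m.to_numpy(),
            "sd": sd.to_numpy(),
            "n": n,
            "ci_low": (m - half).to_numpy(),
            "ci_high": (m + half).to_numpy(),
        }))
    return pd.concat(rows, ignore_index=True)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p via the t transform; NA below 3 points."""
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CongruenceReport:
    """Pairwise effect correlations plus shared/unique categorisation."""

    pair_r: pd.DataFrame  # pair, r, p, n_features
    categories: pd.Series  # feature_id -> category
    subset_r: pd.DataFrame  # category, r, p, n (VLCD vs RYGB means within subset)

    def summary(self) -> str:
        lines = ["Intervention congruence (Pearson r of mean log2 fold changes)"]
        for _, row in self.pair_r.iterrows():
            lines.append(f"  {row['pair']:>13}: r = {row['r']:+.3f} (p = {row['p']:.3g})")
        counts = self.categories.value_counts()
        lines.append("  categories: " + ", ".join(
            f"{c}={int(counts.get(c, 0))}" for c in CATEGORIES))
        for _, row in self.subset_r.iterrows():
            lines.append(
                f"  VLCD-RYGB r within {row['category']}: r = {row['r']:+.3f}"
                f" (n = {int(row['n'])})")
        return "\n".join(lines)


def pairwise_congruence(
    means: pd.DataFrame,
    contrasts: pd.DataFrame,
    alpha: float = 0.05,
) -> CongruenceReport:
    """Correlate mean fold changes between intervention pairs and categorise.

    Parameters
    ----------
    means
        Output of :func:`mean_fold_changes`.
    contrasts
        Mixed-model contrast table containing the vs-SAL q-values
        (pairs like ``VLCD_vs_SAL``).

    Categories partition features: "shared" = q < alpha vs SAL for both VLCD
    and RYGB; "unique_X" = q < alpha for X only; GOP-only significance gets
    "unique_GOP"; everything else "nonsignificant". The VLCD-RYGB mean-FC
    correlation is also recomputed within each category subset (NA when a
    subset has fewer than 3 features).
    """
    wide = means.pivot(index="feature_id", columns="group", values="mean")
    arms = [g for g in ("GOP", "VLCD", "RYGB", "SAL") if g in wide.columns]
    pair_rows = []
    for i, a in enumerate(arms):
        for b in arms[i + 1:]:
            r, p = _pearson(wide[a].to_numpy(), wide[b].to_numpy())
            pair_rows.append((f"{a}_vs_{b}", r, p, len(wide)))
    pair_r = pd.DataFrame(pair_rows, columns=["pair", "r", "p", "n_features"])

    sig = {}
    for g in ("VLCD", "RYGB", "GOP"):
        sub = contrasts[contrasts["pair"] == f"{g}_vs_SAL"].set_index("feature_id")
        sig[g] = sub["q"].reindex(wide.index) < alpha if len(sub) else \
            pd.Series(False, index=wide.index)
    cat = pd.Series("nonsignificant", index=wide.index, name="category")
    cat[sig["GOP"] & ~sig["VLCD"] & ~sig["RYGB"]] = "unique_GOP"
    cat[sig["VLCD"] & ~sig["RYGB"]] = "unique_VLCD"
    cat[sig["RYGB"] & ~sig["VLCD"]] = "unique_RYGB"
    cat[sig["VLCD"] & sig["RYGB"]] = "shared"

    sub_rows = []
    if "VLCD" in wide.columns and "RYGB" in wide.columns:
        for c in CATEGORIES:
            idx = cat.index[cat == c]
            r, p = _pearson(wide.loc[idx, "VLCD"].to_numpy(),
                            wide.loc[idx, "RYGB"].to_numpy())
            sub_rows.append((c, r, p, len(idx)))
    subset_r = pd.DataFrame(sub_rows, columns=["category", "r", "p", "n"])
    return CongruenceReport(pair_r, cat, subset_r)


def clinical_correlations(
    fc: FoldChangeMatrix,
    clinical: ClinicalTable,
    scope: str = "cohort",
    factors: list[str] | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of per-subject fold changes with clinical deltas.

    ``scope`` is "cohort" (all subjects pooled) or "per-group". Returns a
    long table (feature_id, scope, factor, r, p, n, display) where
    ``display`` masks r at unadjusted p < alpha, matching figure-legend
    convention; with ``fdr=True`` a BH q column is added (computed within
    each scope x factor family).
    """
    factors = factors or list(clinical.table.columns)
    scopes: list[tuple[str, pd.Index]]
    common = fc.subjects.intersection(clinical.subjects)
    if scope == "cohort":
        scopes = [("cohort", common)]
    elif scope == "per-group":
        scopes = [(g, common[fc.groups.loc[common] == g]) for g in fc.groups.unique()]
    else:
        raise ValueError("scope must be 'cohort' or 'per-group'")

    out = []
    vals = fc.values
    for sc_name, idx in scopes:
        if len(idx) < 4:
            warnings.warn(f"scope {sc_name!r} has fewer than 4 subjects; skipped")
            continue
        for factor in factors:
            f = clinical.table.loc[idx, factor].to_numpy(dtype=float)
            if np.nanstd(f) == 0:
                warnings.warn(f"factor {factor} constant within scope {sc_name}")
                for fid in fc.features:
                    out.append((fid, sc_name, factor, np.nan, np.nan, len(idx)))
                continue
            block = vals.loc[idx].to_numpy()
            for j, fid in enumerate(fc.features):
                r, p = _pearson(block[:, j], f)
                out.append((fid, sc_name, factor, r, p, len(idx)))
    tab = pd.DataFrame(out, columns=["feature_id", "scope", "factor", "r", "p", "n"])
    tab["display"] = tab["p"] < alpha
    if fdr:
        tab["q"] = np.nan
        for (sc_name, factor), grp in tab.groupby(["scope", "factor"]):
            tab.loc[grp.index, "q"] = bh_fdr(grp["p"].to_numpy())
    return tab
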