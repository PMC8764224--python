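"""Unsupervised overview of intervention response: PCA on fold changes.

``FoldChangePCA`` is a small model object: construct it from a
:class:`~metaboresponse.foldchange.FoldChangeMatrix`, call :meth:`fit`, and
the returned results object carries scores, loadings, explained variance
and one-way between-group score tests.

The decomposition is a plain SVD of the preprocessed (centered, optionally
scaled) matrix with a deterministic sign convention: within each component
the loading of largest magnitude is made positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import GROUPS
from .foldchange import FoldChangeMatrix
from .lme import bh_fdr

__all__ = ["FoldChangePCA", "FoldChangePCAResults"]

PREPROCESSING = ("center", "center_uv", "center_pareto")


class FoldChangePCA:
    """PCA model over a per-subject log2 fold-change matrix.

    Parameters
    ----------
    fc
        Fold-change matrix (missing cells are feature-mean imputed for this
        stage only).
    n_components
        Defaults to min(10, rank bound).
    preprocessing
        "center" (default), "center_uv" (unit variance) or "center_pareto"
        (sqrt-SD scaling). A constant column under scaling gets scale 1 with
        a warning.
    """

    def __init__(
        self,
        fc: FoldChangeMatrix,
        n_components: int | None = None,
        preprocessing: str = "center",
    ) -> None:
        if preprocessing not in PREPROCESSING:
            raise ValueError(f"preprocessing must be one of {PREPROCESSING}")
        self.fc = fc.complete()
        n, p = self.fc.values.shape
        rank_bound = min(n - 1, p)
        self.n_components = min(n_components or 10, rank_bound)
        if self.n_components < 1:
            raise ValueError("need at least 2 subjects and 1 feature")
        self.preprocessing = preprocessing

    def _preprocess(self) -> np.ndarray:
        X = self.fc.values.to_numpy(dtype=float)
        X = X - X.mean(axis=0)
        if self.preprocessing != "center":
            sd = X.std(axis=0, ddof=1)
            zero = sd == 0
            if zero.any():
                warnings.warn(f"{int(zero.sum())} constant column(s): scale set to 1")
                sd = np.where(zero, 1.0, sd)
            X = X / (sd if self.preprocessing == "center_uv" else np.sqrt(sd))
        return X

    def fit(self) -> "FoldChangePCAResults":
        X = self._preprocess()
        n = X.shape[0]
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        k = self.n_components
        U, s, Vt = U[:, :k], s[:k], Vt[:k]
        # sign convention: largest-|loading| element positive per component
        for j in range(k):
            i = int(np.argmax(np.abs(Vt[j])))
            if Vt[j, i] < 0:
                Vt[j] *= -1.0
                U[:, j] *= -1.0
        total_var = float((X ** 2).sum()) / (n - 1)
        evr = (s ** 2 / (n - 1)) / total_var if total_var > 0 else np.zeros(k)
        comp = [f"PC{j + 1}" for j in range(k)]
        scores = pd.DataFrame(U * s, index=self.fc.subjects, columns=comp)
        loadings = pd.DataFrame(Vt.T, index=self.fc.features, columns=comp)
        return FoldChangePCAResults(self, scores, loadings,
                                    pd.Series(evr, index=comp))


@dataclass
class FoldChangePCAResults:
    """Scores, loadings and explained variance of a fitted fold-change PCA."""

    model: FoldChangePCA
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: pd.Series

    def group_tests(self, alpha: float = 0.05) -> pd.DataFrame:
        """One-way between-group analysis per component.

        One-way ANOVA F over the treatment arms plus pairwise Welch t-tests,
        BH-adjusted within each component. Arms with fewer than 2 subjects
        are excluded with a warning.

        Returns a long table: component, test ("anova" or "a_vs_b"),
        statistic, p, q.
        """
        groups = self.model.fc.groups
        counts = groups.value_counts()
        order = [g for g in GROUPS if g in counts.index] + \
            [g for g in counts.index if g not in GROUPS]
        usable = [g for g in order if counts[g] >= 2]
        small = [g for g in order if counts[g] < 2]
        if small:
            warnings.warn(f"excluding group(s) with < 2 subjects: {small}")
        if len(usable) < 2:
            raise ValueError("need >= 2 groups with >= 2 subjects each")
        rows = []
        for comp in self.scores.columns:
            x = self.scores[comp]
            by_group = {g: x[groups == g].to_numpy() for g in usable}
            F, p = stats.f_oneway(*by_group.values())
            rows.append((comp, "anova", float(F), float(p)))
            pair_rows = []
            for i, a in enumerate(usable):
                for b in usable[i + 1:]:
                    t, pp = stats.ttest_ind(by_group[a], by_group[b], equal_var=False)
                    pair_rows.append((comp, f"{a}_vs_{b}", float(t), float(pp)))
            rows.extend(pair_rows)
        out = pd.DataFrame(rows, columns=["component", "test", "statistic", "p"])
        out["q"] = np.nan
        for comp in self.scores.columns:
            mask = (out["component"] == comp) & (out["test"] != "anova")
            out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].tolist())
        return out

    def summary(self) -> str:
        lines = [
            "Fold-change PCA",
            f"  subjects: {len(self.scores)}  features: {len(self.loadings)}",
            f"  preprocessing: {self.model.preprocessing}",
            "  component  explained variance ratio",
        ]
        for comp, v in self.explained_variance_ratio.items():
            lines.append(f"  {comp:>9}  {v:.4f}")
        return "\n".join(lines)

    def plot_scores(self, components=("PC1", "PC2"), ax=None):
        """Scatter of subject scores coloured by treatment arm."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        groups = self.model.fc.groups
        for g in groups.unique():
            m = groups == g
            ax.scatter(self.scores.loc[m, components[0]],
                       self.scores.loc[m, components[1]], label=g, s=20)
        ax.set_xlabel(components[0])
        ax.set_ylabel(components[1])
        ax.legend()
        return ax
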