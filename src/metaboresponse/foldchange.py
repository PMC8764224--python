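"""Per-subject log2 fold-change matrices (week4 / baseline)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import FeatureMatrix, StudyError

__all__ = ["FoldChangeMatrix", "compute_fold_changes"]

logger = logging.getLogger(__name__)


@dataclass
class FoldChangeMatrix:
    """Subjects x features matrix of log2(week4 / baseline) values.

    Rows exist only for subjects with both timepoints present; ``groups``
    carries each row's treatment arm. ``label`` names the biofluid/platform
    grouping the matrix was derived from.
    """

    values: pd.DataFrame
    groups: pd.Series
    label: str = ""

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.groups.index):
            raise StudyError("fold-change rows and group labels disagree")

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def features(self) -> pd.Index:
        return self.values.columns

    def complete(self) -> "FoldChangeMatrix":
        """Feature-wise mean imputation of missing cells (PCA/PLS substrate).

        Restricted to this derived matrix; the underlying intensities are
        never imputed here.
        """
        v = self.values
        if not v.isna().any().any():
            return self
        filled = v.fillna(v.mean(axis=0))
        n = int(v.isna().sum().sum())
        logger.warning("mean-imputed %d missing fold-change cells", n)
        return FoldChangeMatrix(filled, self.groups, self.label)


def compute_fold_changes(
    fm: FeatureMatrix,
    platforms: list[str] | None = None,
    biofluid: str | None = None,
    label: str | None = None,
) -> FoldChangeMatrix:
    """Derive per-subject log2 fold changes for a platform grouping.

    For each subject and feature the value is log2(week4) - log2(baseline).
    Subjects missing either timepoint are dropped and logged. Selecting zero
    features is an error.
    """
    sub = fm.subset(biofluid=biofluid, platforms=platforms) \
        if (platforms is not None or biofluid is not None) else fm
    samples, values = sub.samples, sub.log_values(base=2.0)

    # sample table, not row order, drives the pairing
    by_tp = {
        tp: samples[samples["timepoint"] == tp].reset_index().set_index("subject_id")
        for tp in ("baseline", "week4")
    }
    paired = by_tp["baseline"].index.intersection(by_tp["week4"].index)
    dropped = by_tp["baseline"].index.symmetric_difference(by_tp["week4"].index)
    if len(dropped):
        logger.warning("dropping unpaired subjects from fold changes: %s",
                       sorted(dropped))
    if len(paired) < 2:
        raise StudyError("need paired samples for at least 2 subjects")

    b_ids = by_tp["baseline"].loc[paired, "sample_id"]
    w_ids = by_tp["week4"].loc[paired, "sample_id"]
    fc = values.loc[w_ids].to_numpy() - values.loc[b_ids].to_numpy()
    out = pd.DataFrame(fc, index=pd.Index(paired, name="subject_id"),
                       columns=values.columns)
    groups = by_tp["baseline"].loc[paired, "group"]
    groups.index = out.index
    return FoldChangeMatrix(out, groups, label or (biofluid or "all"))
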