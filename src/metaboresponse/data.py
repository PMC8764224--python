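"""Core study containers: sample metadata, feature matrices, clinical deltas.

A study is a wide intensity table (samples x features), a sample table
mapping each measured sample to (subject, treatment group, timepoint,
biofluid), a feature-annotation table (assay platform, metabolite class,
optional lipid shorthand), and a per-subject clinical table of
baseline-to-week-4 deltas. The sample table — never column order — is
authoritative for the paired design.

Intensities must be strictly positive wherever present so that log
transforms are defined; zeros and negatives are hard errors, not imputed.
Missing values are NaN and may optionally be imputed with half the
per-feature minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lipids import LipidDescriptor, parse_lipid_name

__all__ = [
    "GROUPS",
    "TIMEPOINTS",
    "BIOFLUIDS",
    "PLATFORMS",
    "StudyError",
    "FeatureMatrix",
    "ClinicalTable",
    "read_study",
]

logger = logging.getLogger(__name__)

GROUPS = ("SAL", "GOP", "VLCD", "RYGB")
TIMEPOINTS = ("baseline", "week4")
BIOFLUIDS = ("plasma", "urine")
PLATFORMS = (
    "lipidRPCpos",
    "lipidRPCneg",
    "HILICpos",
    "SmMolRPCpos",
    "SmMolRPCneg",
    "NMR1D",
    "NMRCPMG",
    "IVDr_SmMol",
    "IVDr_lipoprotein",
)

CLINICAL_FACTORS = (
    "delta_weight",
    "delta_fasting_glucose",
    "delta_fasting_insulin",
    "delta_triglycerides",
    "delta_total_cholesterol",
)


class StudyError(ValueError):
    """Hard validation error in study tables (bad label, nonpositive cell, ...)."""


@dataclass
class ClinicalTable:
    """Per-subject week4 - baseline deltas in clinical parameters.

    ``table`` is indexed by subject_id with the five ``delta_*`` columns
    (weight kg, fasting glucose mmol/L, fasting insulin a.u., triglycerides
    mmol/L, total cholesterol mmol/L).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise StudyError(f"duplicate subject rows in clinical table: {dupes}")
        missing = [c for c in CLINICAL_FACTORS if c not in self.table.columns]
        if missing:
            raise StudyError(f"clinical table missing columns {missing}")

    @property
    def subjects(self) -> pd.Index:
        return self.table.index

    def factor(self, name: str) -> pd.Series:
        """Return one delta column; accepts short aliases (weight, glucose, ...)."""
        aliases = {
            "weight": "delta_weight",
            "glucose": "delta_fasting_glucose",
            "insulin": "delta_fasting_insulin",
            "tg": "delta_triglycerides",
            "triglycerides": "delta_triglycerides",
            "chol": "delta_total_cholesterol",
            "cholesterol": "delta_total_cholesterol",
        }
        col = aliases.get(name, name)
        if col not in self.table.columns:
            raise StudyError(f"unknown clinical factor {name!r}")
        return self.table[col]

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="subject_id")

    @classmethod
    def read_csv(cls, path: str | Path) -> "ClinicalTable":
        return cls(pd.read_csv(path, index_col="subject_id", comment="#"))


@dataclass
class FeatureMatrix:
    """Wide intensity matrix with aligned sample and feature metadata.

    Attributes
    ----------
    samples : DataFrame indexed by sample_id with columns
        subject_id, group, timepoint, biofluid.
    features : DataFrame indexed by feature_id with columns
        platform, metabolite_class, name, annotated; a ``lipid`` column of
        parsed :class:`~metaboresponse.lipids.LipidDescriptor` (or None).
    values : DataFrame (sample_id x feature_id) of strictly positive
        intensities; NaN marks missing.
    """

    samples: pd.DataFrame
    features: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        s, f, v = self.samples, self.features, self.values
        if not s.index.equals(v.index):
            raise StudyError("sample table and value rows disagree")
        if not f.index.equals(v.columns):
            raise StudyError("feature table and value columns disagree")
        bad_group = set(s["group"]) - set(GROUPS)
        if bad_group:
            raise StudyError(f"unknown treatment group label(s) {sorted(bad_group)}")
        bad_tp = set(s["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise StudyError(f"unknown timepoint label(s) {sorted(bad_tp)}")
        bad_bf = set(s["biofluid"]) - set(BIOFLUIDS)
        if bad_bf:
            raise StudyError(f"unknown biofluid label(s) {sorted(bad_bf)}")
        key = s[["subject_id", "timepoint", "biofluid"]]
        dup = key.duplicated()
        if dup.any():
            first = key[dup].iloc[0]
            raise StudyError(
                "duplicate (subject, timepoint, biofluid): "
                f"({first.subject_id}, {first.timepoint}, {first.biofluid})"
            )
        ngroup = s.groupby("subject_id")["group"].nunique()
        multi = ngroup[ngroup > 1]
        if len(multi):
            raise StudyError(f"subject(s) in more than one group: {multi.index.tolist()}")
        arr = v.to_numpy(dtype=float)
        nonpos = ~np.isnan(arr) & (arr <= 0)
        if nonpos.any():
            i, j = np.argwhere(nonpos)[0]
            raise StudyError(
                f"nonpositive intensity {arr[i, j]!r} at sample "
                f"{v.index[i]!r}, feature {v.columns[j]!r}"
            )
        unpaired = self.unpaired_subjects()
        if unpaired:
            logger.warning("subjects missing a timepoint: %s", sorted(unpaired))

    def unpaired_subjects(self) -> set[str]:
        """Subjects lacking either timepoint in some biofluid they appear in."""
        out: set[str] = set()
        for (subj, _), grp in self.samples.groupby(["subject_id", "biofluid"]):
            if set(grp["timepoint"]) != set(TIMEPOINTS):
                out.add(subj)
        return out

    # -- convenience ------------------------------------------------------
    @property
    def subjects(self) -> pd.Index:
        return pd.Index(self.samples["subject_id"].unique())

    def subject_groups(self) -> pd.Series:
        """group label per subject_id."""
        return self.samples.drop_duplicates("subject_id").set_index("subject_id")["group"]

    def subset(
        self,
        biofluid: str | None = None,
        platforms: list[str] | None = None,
        features: list[str] | None = None,
    ) -> "FeatureMatrix":
        """Restrict to one biofluid and/or a platform grouping."""
        s, f = self.samples, self.features
        if biofluid is not None:
            s = s[s["biofluid"] == biofluid]
        if platforms is not None:
            f = f[f["platform"].isin(platforms)]
        if features is not None:
            f = f.loc[f.index.intersection(pd.Index(features))]
        if f.empty:
            raise StudyError("selection matches zero features")
        if s.empty:
            raise StudyError("selection matches zero samples")
        return FeatureMatrix(s.copy(), f.copy(), self.values.loc[s.index, f.index].copy())

    def impute_half_min(self) -> "FeatureMatrix":
        """Replace missing (NaN, never zero) values by half the per-feature minimum."""
        v = self.values.copy()
        fill = v.min(axis=0, skipna=True) / 2.0
        v = v.fillna(fill)
        return FeatureMatrix(self.samples.copy(), self.features.copy(), v)

    def log_values(self, base: float = 2.0) -> pd.DataFrame:
        arr = np.log(self.values.to_numpy(dtype=float)) / np.log(base)
        return pd.DataFrame(arr, index=self.values.index, columns=self.values.columns)

    # -- I/O --------------------------------------------------------------
    def write(self, outdir: str | Path, prefix: str = "") -> dict[str, Path]:
        """Write feature/sample/annotation CSVs; returns the paths written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "features": outdir / f"{prefix}intensities.csv",
            "samples": outdir / f"{prefix}samples.csv",
            "annotation": outdir / f"{prefix}annotation.csv",
        }
        self.values.to_csv(paths["features"], index_label="sample_id")
        self.samples.to_csv(paths["samples"], index_label="sample_id")
        ann = self.features.drop(columns=["lipid"], errors="ignore")
        ann.to_csv(paths["annotation"], index_label="feature_id")
        return paths


def _canonical_sample_order(samples: pd.DataFrame) -> pd.Index:
    order = samples.sort_values(
        ["biofluid", "subject_id", "timepoint"], kind="stable"
    ).index
    return order


def read_study(
    feature_csv: str | Path,
    sample_csv: str | Path,
    annotation_csv: str | Path,
    clinical_csv: str | Path | None = None,
    sep: str | None = None,
) -> tuple[FeatureMatrix, ClinicalTable | None]:
    """Read and validate a study from its four CSV/TSV tables.

    Row order is canonicalised by (biofluid, subject, timepoint); the sample
    table is authoritative for sample identity. Features present in the
    intensity table but absent from the annotation table are retained with
    ``annotated=False``. Lipid shorthand in the annotation ``name`` column is
    parsed; unparseable names are kept with ``lipid=None`` and a warning.
    """
    kw = dict(comment="#")
    if sep is None:
        kw["sep"] = None
        kw["engine"] = "python"
    else:
        kw["sep"] = sep
    values = pd.read_csv(feature_csv, index_col="sample_id", **kw)
    samples = pd.read_csv(sample_csv, index_col="sample_id", **kw)
    ann = pd.read_csv(annotation_csv, index_col="feature_id", **kw)

    missing = values.index.difference(samples.index)
    if len(missing):
        raise StudyError(f"samples missing from sample table: {missing.tolist()[:5]}")
    samples = samples.loc[values.index]

    features = ann.reindex(values.columns)
    features["platform"] = features.get("platform", pd.Series(dtype=object)).fillna("NMR1D")
    features["metabolite_class"] = features.get(
        "metabolite_class", pd.Series(dtype=object)
    ).fillna("other")
    if "name" not in features.columns:
        features["name"] = features.index
    features["name"] = features["name"].fillna(pd.Series(features.index, index=features.index))
    if "annotated" in features.columns:
        features["annotated"] = features["annotated"].astype(object).apply(
            lambda x: bool(x) if pd.notna(x) else False)
    else:
        features["annotated"] = features.index.isin(ann.index)
    features.loc[features.index.difference(ann.index), "annotated"] = False
    features["lipid"] = [
        parse_lipid_name(n) if _looks_like_lipid(n) else None for n in features["name"]
    ]

    order = _canonical_sample_order(samples)
    fm = FeatureMatrix(samples.loc[order], features, values.loc[order])

    clinical = None
    if clinical_csv is not None:
        clinical = ClinicalTable.read_csv(clinical_csv)
    return fm, clinical


def _looks_like_lipid(name: object) -> bool:
    from .lipids import _NAME_RE, _CANON  # shared grammar

    if not isinstance(name, str):
        return False
    m = _NAME_RE.match(name)
    return bool(m) and m.group(1).upper() in _CANON
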