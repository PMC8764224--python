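"""Synthetic intervention-study generator with known ground truth.

Emulates a four-arm (SAL / GOP / VLCD / RYGB) paired-design metabolomic
study: each subject contributes a baseline and a week-4 sample per biofluid,
log2 intensities follow a random-intercept model

    y[s, f] = mu_f + b_subject + drift_f * w4 + delta[f, g] * w4
              + slope * clinical_delta * w4 + eps,      intensity = 2 ** y

with subject intercepts b ~ N(0, sigma_subject^2) and residuals
eps ~ N(0, sigma_resid^2), both on the log2 scale. ``delta[f, g]`` is the
group-by-time effect the downstream mixed models estimate; the VLCD and
RYGB effect vectors are drawn from a bivariate normal with configurable
correlation so that intervention congruence is a known quantity. GOP alters
only an explicitly listed (default empty) feature set, and SAL carries no
treatment effect beyond a small common drift shared by all arms.

Clinical week-4 deltas (weight, glucose, insulin, triglycerides,
cholesterol) are drawn per arm; selected features can be linked to a
clinical factor so correlation and confounder-adjustment analyses have a
recoverable target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    BIOFLUIDS,
    CLINICAL_FACTORS,
    GROUPS,
    ClinicalTable,
    FeatureMatrix,
    StudyError,
)
from .lipids import Chain, LipidDescriptor, format_lipid_name, parse_lipid_name

__all__ = [
    "DEFAULT_GROUP_SIZES",
    "EffectSpec",
    "NoiseSpec",
    "ClinicalSpec",
    "GroundTruth",
    "make_feature_annotation",
    "caloric_restriction_template",
    "simulate_study",
    "write_study",
]

#: Arm sizes of the emulated cohort (68 subjects in total).
DEFAULT_GROUP_SIZES: dict[str, int] = {"SAL": 11, "GOP": 14, "VLCD": 22, "RYGB": 21}


@dataclass
class EffectSpec:
    """Group-by-time effect structure on the log2 scale.

    Parameters
    ----------
    frac_affected
        Proportion of features with a nonzero VLCD/RYGB effect (default one
        third, the upper end of the fraction of features altered by these
        interventions).
    congruence_rho
        Target correlation between the VLCD and RYGB effect vectors over
        affected features.
    effect_sizes
        Pool of |delta| magnitudes (log2 units) sampled per affected feature.
    gop_effect_features
        Features given a GOP effect (mapping feature_id -> delta); empty by
        default, mirroring an intervention that alters almost nothing.
    sal_drift_sd
        SD of a per-feature time drift common to every arm (cancels in
        interaction contrasts).
    signs
        Optional per-feature sign template (DataFrame with VLCD/RYGB columns
        in {-1, 0, +1}); when given, affected features are those with a
        nonzero sign and magnitudes are |bivariate normal| draws.
    delta
        Fully explicit effect matrix (features x groups); overrides all of
        the above when provided.
    """

    frac_affected: float = 1.0 / 3.0
    congruence_rho: float = 0.9
    effect_sizes: tuple[float, ...] = (0.5, 1.0)
    gop_effect_features: dict[str, float] = field(default_factory=dict)
    sal_drift_sd: float = 0.05
    signs: pd.DataFrame | None = None
    delta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.congruence_rho <= 1.0:
            raise ValueError("congruence_rho must lie in [-1, 1]")
        if not 0.0 <= self.frac_affected <= 1.0:
            raise ValueError("frac_affected must lie in [0, 1]")

    @classmethod
    def null(cls) -> "EffectSpec":
        """No treatment effects at all (for calibration studies)."""
        return cls(frac_affected=0.0, sal_drift_sd=0.0)


@dataclass
class NoiseSpec:
    """Variance components of the log2 intensity model."""

    sigma_subject: float = 0.8
    sigma_resid: float = 0.4
    baseline_mu_range: tuple[float, float] = (8.0, 20.0)

    def __post_init__(self) -> None:
        if self.sigma_subject < 0 or self.sigma_resid < 0:
            raise ValueError("noise SDs must be nonnegative")

    @classmethod
    def null(cls) -> "NoiseSpec":
        return cls(sigma_subject=0.0, sigma_resid=0.0)


#: Per-arm (mean, sd) of clinical week-4 deltas. Weight loss deepens from
#: SAL to RYGB; glucose lowering is largest in the GOP arm; triglycerides
#: fall with VLCD but rise slightly with RYGB. Qualitative-pattern defaults,
#: overridable per study.
DEFAULT_CLINICAL = {
    "delta_weight": {"SAL": (-2.0, 1.5), "GOP": (-4.0, 2.0), "VLCD": (-8.0, 2.5), "RYGB": (-10.0, 2.5)},
    "delta_fasting_glucose": {"SAL": (-0.1, 0.5), "GOP": (-1.6, 0.6), "VLCD": (-0.9, 0.6), "RYGB": (-1.2, 0.6)},
    "delta_fasting_insulin": {"SAL": (-2.0, 8.0), "GOP": (-20.0, 10.0), "VLCD": (-25.0, 10.0), "RYGB": (-30.0, 10.0)},
    "delta_triglycerides": {"SAL": (0.0, 0.3), "GOP": (-0.1, 0.3), "VLCD": (-0.4, 0.3), "RYGB": (0.2, 0.3)},
    "delta_total_cholesterol": {"SAL": (0.0, 0.4), "GOP": (-0.2, 0.4), "VLCD": (-0.6, 0.4), "RYGB": (-0.3, 0.4)},
}


@dataclass
class ClinicalSpec:
    """Per-arm normal (mean, sd) for each clinical delta."""

    params: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLINICAL.items()})


@dataclass
class GroundTruth:
    """Everything the generator knows and downstream stages must recover."""

    delta: pd.DataFrame  # features x groups, log2 group-by-time effects
    drift: pd.Series  # per-feature common time drift
    affected: list[str]  # features with nonzero VLCD/RYGB effect
    realized_rho: float  # empirical corr of VLCD vs RYGB deltas (affected set)
    linked: dict[str, tuple[str, float]]  # feature -> (clinical factor, slope)

    def to_frame(self) -> pd.DataFrame:
        out = self.delta.copy()
        out["drift"] = self.drift
        out["affected"] = out.index.isin(self.affected)
        out["linked_factor"] = [self.linked.get(f, (None, np.nan))[0] for f in out.index]
        out["linked_slope"] = [self.linked.get(f, (None, np.nan))[1] for f in out.index]
        return out


# ---------------------------------------------------------------------------
# feature annotation
# ---------------------------------------------------------------------------

_ACYL_POOL = [(14, 0), (16, 0), (16, 1), (18, 0), (18, 1), (18, 2), (20, 4),
              (22, 6), (24, 0), (26, 0)]
_SN1_POOL = [(16, 0), (18, 0), (18, 1)]
_BASE_POOL = [(18, 1), (16, 1)]
_AMINO_ACIDS = ["alanine", "glycine", "valine", "leucine", "isoleucine",
                "tyrosine", "phenylalanine", "glutamic acid", "serine", "proline"]
_KETONES = ["3-hydroxybutyric acid", "acetoacetic acid"]
_TCA = ["citric acid", "succinic acid", "pyruvic acid"]
_OTHER_SMALL = ["TMAO", "caffeine", "trigonelline", "paraxanthine", "creatine",
                "pantothenate", "kynurenine", "suberic acid", "indoxyl glucuronide"]

_PLASMA_CLASS_FREQ = [
    ("triacylglycerol", 0.14),
    ("phosphatidylcholine", 0.12),
    ("lysophospholipid", 0.08),
    ("ceramide", 0.04),
    ("sphingomyelin", 0.05),
    ("fatty acid", 0.08),
    ("acylcarnitine", 0.05),
    ("amino acid", 0.06),
    ("ketone body", 0.02),
    ("TCA intermediate", 0.02),
    ("other", 0.06),
    ("unannotated", 0.28),
]
_URINE_CLASS_FREQ = [
    ("amino acid", 0.10),
    ("ketone body", 0.03),
    ("TCA intermediate", 0.04),
    ("other", 0.18),
    ("unannotated", 0.65),
]


def _lipid_name(cls: str, rng: np.random.Generator) -> str:
    if cls == "fatty acid":
        c, d = _ACYL_POOL[rng.integers(len(_ACYL_POOL))]
        return f"FA({c}:{d})"
    if cls == "acylcarnitine":
        c, d = _ACYL_POOL[rng.integers(len(_ACYL_POOL))]
        return f"CAR({c}:{d})"
    if cls == "triacylglycerol":
        c = int(rng.integers(42, 58))
        d = int(rng.integers(0, 5))
        return f"TG({c}:{d})"
    if cls == "phosphatidylcholine":
        c1, d1 = _SN1_POOL[rng.integers(len(_SN1_POOL))]
        c2, d2 = _ACYL_POOL[rng.integers(len(_ACYL_POOL))]
        return f"PC({c1}:{d1}/{c2}:{d2})"
    if cls == "lysophospholipid":
        sub = ["LPC", "LPE", "LPI", "LPA"][rng.integers(4)]
        c, d = _ACYL_POOL[rng.integers(len(_ACYL_POOL))]
        return f"{sub}({c}:{d})"
    if cls == "ceramide":
        cb, db = _BASE_POOL[rng.integers(len(_BASE_POOL))]
        c, d = _ACYL_POOL[rng.integers(len(_ACYL_POOL))]
        return f"Cer(d{cb}:{db}/{c}:{d})"
    if cls == "sphingomyelin":
        cb, db = _BASE_POOL[rng.integers(len(_BASE_POOL))]
        c, d = _ACYL_POOL[rng.integers(len(_ACYL_POOL))]
        return f"SM(d{cb}:{db}/{c}:{d})"
    raise ValueError(cls)


def make_feature_annotation(
    n_features: int,
    seed: int | np.random.Generator = 0,
    biofluid: str = "plasma",
) -> pd.DataFrame:
    """Generate a feature-annotation table with realistic class proportions.

    Lipid classes receive parseable shorthand names drawn from common acyl
    chain pools so that acyl-chain matching finds partners; small molecules
    get names recognised by :func:`caloric_restriction_template`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freq = _PLASMA_CLASS_FREQ if biofluid == "plasma" else _URINE_CLASS_FREQ
    classes = [c for c, _ in freq]
    probs = np.array([p for _, p in freq])
    probs = probs / probs.sum()
    draws = rng.choice(len(classes), size=n_features, p=probs)

    if biofluid == "plasma":
        lc_platforms = ("lipidRPCpos", "lipidRPCneg")
        sm_platform = "HILICpos"
        global_platform = "HILICpos"
    else:
        lc_platforms = ("SmMolRPCpos", "SmMolRPCneg")
        sm_platform = "IVDr_SmMol"
        global_platform = "SmMolRPCpos"

    rows = []
    for i, k in enumerate(draws):
        cls = classes[k]
        fid = f"{biofluid[0].upper()}F{i:04d}"
        if cls == "unannotated":
            rows.append((fid, global_platform, "other", fid, False))
        elif cls in ("amino acid",):
            rows.append((fid, sm_platform, cls, _AMINO_ACIDS[rng.integers(len(_AMINO_ACIDS))], True))
        elif cls == "ketone body":
            rows.append((fid, sm_platform, cls, _KETONES[rng.integers(len(_KETONES))], True))
        elif cls == "TCA intermediate":
            rows.append((fid, sm_platform, cls, _TCA[rng.integers(len(_TCA))], True))
        elif cls == "other":
            rows.append((fid, sm_platform, cls, _OTHER_SMALL[rng.integers(len(_OTHER_SMALL))], True))
        else:
            rows.append((fid, lc_platforms[int(rng.integers(2))], cls, _lipid_name(cls, rng), True))
    features = pd.DataFrame(
        rows, columns=["feature_id", "platform", "metabolite_class", "name", "annotated"]
    ).set_index("feature_id")
    features["lipid"] = [
        parse_lipid_name(n) if features.loc[f, "annotated"] and _is_lipid_class(c) else None
        for f, n, c in zip(features.index, features["name"], features["metabolite_class"])
    ]
    return features


_LIPID_CLASS_SET = {
    "fatty acid", "acylcarnitine", "triacylglycerol", "phosphatidylcholine",
    "lysophospholipid", "ceramide", "sphingomyelin",
}


def _is_lipid_class(cls: str) -> bool:
    return cls in _LIPID_CLASS_SET


# ---------------------------------------------------------------------------
# caloric-restriction effect template
# ---------------------------------------------------------------------------

_CLASS_SIGNS = {
    "triacylglycerol": -1,
    "fatty acid": +1,
    "acylcarnitine": +1,
    "phosphatidylcholine": -1,
    "lysophospholipid": -1,
    "ketone body": +1,
    "TCA intermediate": +1,
}
_RYGB_EXTRA_NEG = {"valine", "leucine", "isoleucine", "tyrosine",
                   "caffeine", "trigonelline", "paraxanthine"}
_RYGB_EXTRA_POS = {"TMAO"}


def caloric_restriction_template(features: pd.DataFrame) -> pd.DataFrame:
    """Signed VLCD/RYGB effect-direction template from metabolite classes.

    Encodes the energetic switch to beta oxidation: acylglycerols down,
    free fatty acids and acylcarnitines up, phospholipids and their
    lysophospholipid derivatives down, ketone bodies and TCA intermediates
    up. Very-long-chain (>= C24) fatty species flip to negative. The RYGB
    column additionally lowers BCAAs, tyrosine and caffeine metabolites and
    raises TMAO. Unknown classes stay at zero.

    Returns a features x {VLCD, RYGB} DataFrame of signs in {-1, 0, +1}.
    """
    signs = pd.DataFrame(0, index=features.index, columns=["VLCD", "RYGB"], dtype=int)
    for fid, row in features.iterrows():
        s = _CLASS_SIGNS.get(row["metabolite_class"], 0)
        lip = row.get("lipid")
        if s != 0 and isinstance(lip, LipidDescriptor) and lip.lipid_class in ("FA", "CAR") \
                and lip.very_long_chain:
            s = -1  # very-long-chain fatty species fall while shorter ones rise
        signs.loc[fid, ["VLCD", "RYGB"]] = s
        name = str(row.get("name", ""))
        if name in _RYGB_EXTRA_NEG:
            signs.loc[fid, "RYGB"] = -1
        elif name in _RYGB_EXTRA_POS:
            signs.loc[fid, "RYGB"] = +1
    return signs


# ---------------------------------------------------------------------------
# effect realisation and study simulation
# ---------------------------------------------------------------------------

def _realize_effects(
    features: pd.DataFrame, effect: EffectSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[str], float]:
    n = len(features)
    delta = pd.DataFrame(0.0, index=features.index, columns=list(GROUPS))
    if effect.delta is not None:
        delta.loc[effect.delta.index, effect.delta.columns] = effect.delta
        aff = delta.index[(delta[["VLCD", "RYGB"]] != 0).any(axis=1)].tolist()
    else:
        rho = effect.congruence_rho
        cov = np.array([[1.0, rho], [rho, 1.0]])
        if effect.signs is not None:
            aff = features.index[(effect.signs != 0).any(axis=1)].tolist()
        else:
            k = int(round(effect.frac_affected * n))
            aff = list(rng.choice(features.index.to_numpy(), size=k, replace=False))
        if aff:
            z = rng.multivariate_normal([0.0, 0.0], cov, size=len(aff))
            mags = rng.choice(np.asarray(effect.effect_sizes, dtype=float), size=len(aff))
            if effect.signs is not None:
                sv = effect.signs.loc[aff, "VLCD"].to_numpy()
                sr = effect.signs.loc[aff, "RYGB"].to_numpy()
                delta.loc[aff, "VLCD"] = sv * mags * np.abs(z[:, 0])
                delta.loc[aff, "RYGB"] = sr * mags * np.abs(z[:, 1])
            else:
                delta.loc[aff, "VLCD"] = mags * z[:, 0]
                delta.loc[aff, "RYGB"] = mags * z[:, 1]
        for fid, d in effect.gop_effect_features.items():
            delta.loc[fid, "GOP"] = d
    if len(aff) >= 3:
        dv = delta.loc[aff, "VLCD"].to_numpy()
        dr = delta.loc[aff, "RYGB"].to_numpy()
        with np.errstate(invalid="ignore"):
            realized = float(np.corrcoef(dv, dr)[0, 1])
    else:
        realized = float("nan")
    return delta, aff, realized


def simulate_study(
    n_per_group: dict[str, int] | None = None,
    n_features: int = 500,
    effect: EffectSpec | None = None,
    noise: NoiseSpec | None = None,
    clinical_link: dict[str, tuple[str, float]] | None = None,
    seed: int = 0,
    biofluid: str = "plasma",
    features: pd.DataFrame | None = None,
    clinical: ClinicalSpec | None = None,
) -> tuple[FeatureMatrix, ClinicalTable, GroundTruth]:
    """Simulate one complete paired study with known ground truth.

    Parameters
    ----------
    n_per_group
        Subjects per arm; defaults to the emulated cohort
        (SAL 11, GOP 14, VLCD 22, RYGB 21).
    clinical_link
        ``{feature_id: (clinical factor, slope)}``: the subject's clinical
        delta times slope is added to that feature's week-4 log2 value, so
        the feature's fold change tracks the clinical response.
    features
        Optional pre-built annotation table (e.g. to pair with
        :func:`caloric_restriction_template`); generated when omitted.

    Returns
    -------
    (FeatureMatrix, ClinicalTable, GroundTruth)
        Same seed reproduces the study bit-for-bit.
    """
    n_per_group = dict(n_per_group or DEFAULT_GROUP_SIZES)
    for g, ng in n_per_group.items():
        if g not in GROUPS:
            raise StudyError(f"unknown group {g!r}")
        if ng <= 0:
            raise StudyError(f"group size must be positive, got {g}={ng}")
    effect = effect if effect is not None else EffectSpec()
    noise = noise if noise is not None else NoiseSpec()
    clinical = clinical if clinical is not None else ClinicalSpec()
    clinical_link = dict(clinical_link or {})

    rng = np.random.default_rng(seed)
    # Fixed substream order keeps ground truth identical across noise seeds.
    rng_truth, rng_clin, rng_noise = (
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3)
    )

    if features is None:
        features = make_feature_annotation(n_features, rng_truth, biofluid=biofluid)
    else:
        features = features.copy()
        n_features = len(features)

    delta, affected, realized_rho = _realize_effects(features, effect, rng_truth)
    mu = rng_truth.uniform(*noise.baseline_mu_range, size=n_features)
    drift = pd.Series(
        rng_truth.normal(0.0, effect.sal_drift_sd, size=n_features)
        if effect.sal_drift_sd > 0 else np.zeros(n_features),
        index=features.index,
    )

    # subjects and clinical deltas
    sub_rows = []
    for g in GROUPS:
        for i in range(n_per_group.get(g, 0)):
            sub_rows.append((f"{g}{i:02d}", g))
    subjects = pd.DataFrame(sub_rows, columns=["subject_id", "group"]).set_index("subject_id")
    clin = pd.DataFrame(index=subjects.index, columns=list(CLINICAL_FACTORS), dtype=float)
    for factor in CLINICAL_FACTORS:
        for g in GROUPS:
            m, s = clinical.params[factor][g]
            idx = subjects.index[subjects["group"] == g]
            clin.loc[idx, factor] = rng_clin.normal(m, s, size=len(idx))
    clinical_table = ClinicalTable(clin)

    # samples: (biofluid, subject, timepoint) canonical order
    srows = []
    for sid, row in subjects.iterrows():
        for tp in ("baseline", "week4"):
            srows.append((f"{sid}_{biofluid}_{tp}", sid, row["group"], tp, biofluid))
    samples = pd.DataFrame(
        srows, columns=["sample_id", "subject_id", "group", "timepoint", "biofluid"]
    ).set_index("sample_id")

    nsub = len(subjects)
    b = rng_noise.normal(0.0, noise.sigma_subject, size=(nsub, n_features))
    eps = rng_noise.normal(0.0, noise.sigma_resid, size=(2 * nsub, n_features))
    dmat = delta.to_numpy()
    gidx = {g: j for j, g in enumerate(GROUPS)}

    y = np.empty((2 * nsub, n_features))
    for i, sid in enumerate(subjects.index):
        g = subjects.loc[sid, "group"]
        base = mu + b[i]
        week4 = base + drift.to_numpy() + dmat[:, gidx[g]]
        for fid, (factor, slope) in clinical_link.items():
            j = features.index.get_loc(fid)
            week4[j] = week4[j] + slope * clin.loc[sid, _factor_col(factor)]
        y[2 * i] = base + eps[2 * i]
        y[2 * i + 1] = week4 + eps[2 * i + 1]

    values = pd.DataFrame(
        np.exp2(y), index=samples.index, columns=features.index
    )
    fm = FeatureMatrix(samples, features, values)
    truth = GroundTruth(delta=delta, drift=drift, affected=affected,
                        realized_rho=realized_rho, linked=clinical_link)
    return fm, clinical_table, truth


def _factor_col(name: str) -> str:
    aliases = {
        "weight": "delta_weight",
        "glucose": "delta_fasting_glucose",
        "insulin": "delta_fasting_insulin",
        "tg": "delta_triglycerides",
        "chol": "delta_total_cholesterol",
    }
    col = aliases.get(name, name)
    if col not in CLINICAL_FACTORS:
        raise StudyError(f"unknown clinical factor {name!r}")
    return col


def write_study(
    outdir: str | Path,
    fm: FeatureMatrix,
    clinical: ClinicalTable,
    truth: GroundTruth | None = None,
    prefix: str = "",
) -> dict[str, Path]:
    """Write the four study CSVs (plus ground truth when given)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = fm.write(outdir, prefix=prefix)
    paths["clinical"] = outdir / f"{prefix}clinical.csv"
    clinical.write_csv(paths["clinical"])
    if truth is not None:
        paths["ground_truth"] = outdir / f"{prefix}ground_truth.csv"
        truth.to_frame().to_csv(paths["ground_truth"], index_label="feature_id")
    return paths
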