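"""Config-driven orchestration of the full analysis pipeline.

One YAML config names either a ``simulate`` block or the four input CSVs,
the platform groupings, and per-stage parameters. ``run_pipeline`` executes
simulate/ingest -> fold-change PCA -> mixed models -> PLS -> congruence ->
chain matching, writes every stage output as CSV (each with a provenance
header comment carrying the config hash and seed) plus a markdown report,
and is byte-deterministic given (config, seed).

All randomness flows from the root seed through named substreams, one per
stage, so adding a stage never perturbs another stage's stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .congruence import clinical_correlations, mean_fold_changes, pairwise_congruence
from .data import ClinicalTable, FeatureMatrix, StudyError, read_study
from .foldchange import compute_fold_changes
from .lme import InteractionMixedLM, power_simulation
from .matching import build_matches, match_covariation
from .pca import FoldChangePCA
from .pls import PLSRegression1
from .simulate import EffectSpec, NoiseSpec, simulate_study, write_study

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGE_SEED_OFFSETS = {"simulate": 11, "pca": 23, "pls": 37, "power": 53}


def _stage_seed(root: int, stage: str) -> int:
    # named substreams: stable small seeds derived from the root
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    out_dir: str = "metaboresponse_run"
    alpha: float = 0.05
    simulate: dict | None = None
    inputs: dict | None = None
    groupings: dict = field(default_factory=dict)
    pca: dict = field(default_factory=dict)
    lme: dict = field(default_factory=dict)
    pls: dict = field(default_factory=dict)
    chain_match: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise StudyError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.alpha <= 0 or self.alpha >= 1:
            raise StudyError("alpha must lie in (0, 1)")
        if (self.simulate is None) == (self.inputs is None):
            raise StudyError("config needs exactly one of 'simulate' or 'inputs'")
        if self.pls:
            thr = self.pls.get("q2_threshold", 0.15)
            pthr = self.pls.get("perm_p_threshold", 0.01)
            if thr <= 0 or pthr <= 0:
                raise StudyError("PLS thresholds must be positive")
            if self.inputs is not None and "clinical_csv" not in self.inputs:
                raise StudyError("PLS stage requested but no clinical table configured")

    def content_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig, index: bool = False,
               index_label: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# metaboresponse {__version__} config_hash={cfg.content_hash()} "
                 f"seed={cfg.seed}\n")
        df.to_csv(fh, index=index, index_label=index_label, lineterminator="\n")


def _load_or_simulate(cfg: RunConfig, outdir: Path):
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        effect = EffectSpec(
            frac_affected=sim.get("frac_affected", 1.0 / 3.0),
            congruence_rho=sim.get("rho", 0.9),
            effect_sizes=tuple(sim.get("effect_sizes", (0.5, 1.0))),
        )
        noise = NoiseSpec(
            sigma_subject=sim.get("sigma_subject", 0.8),
            sigma_resid=sim.get("sigma_resid", 0.4),
        )
        link = {k: tuple(v) for k, v in sim.get("clinical_link", {}).items()}
        fm, clinical, truth = simulate_study(
            n_per_group=sim.get("n_per_group"),
            n_features=sim.get("n_features", 300),
            effect=effect,
            noise=noise,
            clinical_link=link,
            seed=_stage_seed(cfg.seed, "simulate"),
            biofluid=sim.get("biofluid", "plasma"),
        )
        write_study(outdir / "study", fm, clinical, truth)
        return fm, clinical
    inp = cfg.inputs
    required = ("feature_csv", "sample_csv", "annotation_csv")
    missing = [k for k in required if k not in inp]
    if missing:
        raise StudyError(f"inputs block missing {missing}")
    return read_study(
        inp["feature_csv"], inp["sample_csv"], inp["annotation_csv"],
        inp.get("clinical_csv"),
    )


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every configured stage; returns the report directory."""
    logging.basicConfig(level=cfg.log_level)
    cfg.validate()
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: list[str] = [
        "# metaboresponse pipeline report",
        "",
        f"- version: {__version__}",
        f"- config hash: `{cfg.content_hash()}`",
        f"- seed: {cfg.seed}",
        "",
    ]

    fm, clinical = _load_or_simulate(cfg, outdir)
    gcounts = {g: int(n) for g, n in fm.subject_groups().value_counts().items()}
    report.append(f"Study: {len(fm.subjects)} subjects, "
                  f"{len(fm.features)} features, groups {gcounts}")

    groupings = cfg.groupings or {"all": None}
    pls_validity_rows = []
    for gname, platforms in groupings.items():
        fc = compute_fold_changes(fm, platforms=platforms, label=gname)

        # --- fold-change PCA -------------------------------------------
        pca_res = FoldChangePCA(
            fc, n_components=cfg.pca.get("n_components"),
            preprocessing=cfg.pca.get("preprocessing", "center"),
        ).fit()
        _write_csv(pca_res.scores, outdir / f"{gname}_scores.csv", cfg,
                   index=True, index_label="subject_id")
        _write_csv(pca_res.loadings, outdir / f"{gname}_loadings.csv", cfg,
                   index=True, index_label="feature_id")
        _write_csv(pca_res.explained_variance_ratio.rename("evr").to_frame(),
                   outdir / f"{gname}_explained_variance.csv", cfg,
                   index=True, index_label="component")
        tests = pca_res.group_tests(alpha=cfg.alpha)
        _write_csv(tests, outdir / f"{gname}_score_tests.csv", cfg)

        # --- mixed models ----------------------------------------------
        lme_res = InteractionMixedLM(fm.subset(platforms=platforms)
                                     if platforms else fm).fit()
        con = lme_res.contrasts(cfg.lme.get("contrasts", "vs_sal"))
        _write_csv(con, outdir / f"{gname}_contrasts.csv", cfg)
        pct = lme_res.percent_significant(cfg.alpha,
                                          cfg.lme.get("contrasts", "vs_sal"))
        _write_csv(pct.rename("pct_significant").to_frame(),
                   outdir / f"{gname}_summary.csv", cfg,
                   index=True, index_label="pair")
        report += ["", f"## Grouping `{gname}`", "",
                   f"Percent of features significant (q < {cfg.alpha}):", ""]
        report += [f"- {pair}: {v:.1f}%" for pair, v in pct.items()]

        adjust = cfg.lme.get("adjust_for", [])
        if adjust and clinical is None:
            raise StudyError("adjusted models requested but no clinical table")
        for factor in adjust:
            adj = InteractionMixedLM(
                fm.subset(platforms=platforms) if platforms else fm,
                adjust_factor=clinical.factor(factor),
            ).fit()
            sens = lme_res.confounder_sensitive(adj, alpha=cfg.alpha)
            _write_csv(sens, outdir / f"{gname}_adjusted_{factor}.csv", cfg)

        # --- congruence -------------------------------------------------
        means = mean_fold_changes(fc)
        _write_csv(means, outdir / f"{gname}_mean_fc.csv", cfg)
        cong = pairwise_congruence(means, con, alpha=cfg.alpha)
        _write_csv(cong.pair_r, outdir / f"{gname}_congruence.csv", cfg)
        _write_csv(cong.categories.rename("category").reset_index(),
                   outdir / f"{gname}_categories.csv", cfg)
        report += ["", "Mean fold-change congruence:", ""]
        report += [f"- {row['pair']}: r = {row['r']:+.3f}"
                   for _, row in cong.pair_r.iterrows()]

        if clinical is not None:
            cc = clinical_correlations(fc, clinical, scope="cohort",
                                       alpha=cfg.alpha)
            _write_csv(cc, outdir / f"{gname}_clinical_corr.csv", cfg)

        # --- PLS --------------------------------------------------------
        if cfg.pls and clinical is not None:
            fcc = fc.complete()
            common = fcc.subjects.intersection(clinical.subjects)
            for factor in cfg.pls.get("factors", ["weight"]):
                y = clinical.factor(factor).loc[common]
                model = PLSRegression1(
                    fcc.values.loc[common], y,
                    n_components=cfg.pls.get("n_components", 2),
                    cv_folds=cfg.pls.get("folds", 7),
                    seed=_stage_seed(cfg.seed, "pls"),
                    groups=fcc.groups.loc[common],
                )
                res = model.fit()
                rep = res.permutation_test(
                    B=cfg.pls.get("B", 200),
                    seed=_stage_seed(cfg.seed, "pls"),
                    q2_threshold=cfg.pls.get("q2_threshold", 0.15),
                    perm_p_threshold=cfg.pls.get("perm_p_threshold", 0.01),
                )
                pls_validity_rows.append({
                    "grouping": gname, "factor": factor,
                    "n_components": res.weights.shape[1],
                    "r2y": res.r2y, "q2y": res.q2y,
                    "perm_p": rep.perm_p, "valid": rep.valid,
                })
                sel = rep.feature_table[rep.feature_table["selected"]]
                _write_csv(sel.reset_index(names="feature_id"),
                           outdir / f"{gname}_pls_selected_{factor}.csv", cfg)

        # --- chain matching --------------------------------------------
        if cfg.chain_match:
            matches = build_matches(fm.features)
            _write_csv(matches, outdir / f"{gname}_matches.csv", cfg)
            points, class_r = match_covariation(matches, means)
            _write_csv(points, outdir / f"{gname}_covariation_points.csv", cfg)
            _write_csv(class_r, outdir / f"{gname}_covariation.csv", cfg)
            if len(class_r):
                report += ["", "Chain-match co-variation (Pearson r per partner class):",
                           ""]
                report += [
                    f"- {row['partner_class']}: r = {row['r']:+.3f}"
                    f" (n = {int(row['n_points'])})"
                    for _, row in class_r.iterrows() if np.isfinite(row["r"])
                ]

    if pls_validity_rows:
        pls_tab = pd.DataFrame(pls_validity_rows)
        _write_csv(pls_tab, outdir / "pls_models.csv", cfg)
        report += ["", "## PLS validity", ""]
        report += [
            f"- {r['grouping']}/{r['factor']}: Q2Y = {r['q2y']:.3f}, "
            f"perm p = {r['perm_p']:.4g}, valid = {r['valid']}"
            for r in pls_validity_rows
        ]

    (outdir / "report.md").write_text("\n".join(report) + "\n")
    return outdir
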