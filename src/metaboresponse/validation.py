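"""Operating-characteristic studies of the whole pipeline.

Each function here defines one simulation study with known ground truth,
runs the relevant pipeline stage at full size, and returns the measured
operating characteristics (false-discovery calibration, estimator bias and
coverage, detection rates, recovery of the designed effect correlation,
...). They are the package's own validation battery: the test suite asserts
the expected properties on their outputs, and the reproduction script
re-reports the same numbers.

All studies run on the emulated cohort design (arms SAL 11 / GOP 14 /
VLCD 22 / RYGB 21, paired baseline/week-4 plasma samples) unless a
condition explicitly needs a different shape; every function takes a root
seed and derives per-replicate seeds from it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .congruence import mean_fold_changes, pairwise_congruence
from .data import GROUPS
from .foldchange import compute_fold_changes
from .lme import InteractionMixedLM
from .matching import build_matches, match_covariation
from .pca import FoldChangePCA
from .pls import PLSRegression1, q2y_cv
from .simulate import (
    EffectSpec,
    NoiseSpec,
    caloric_restriction_template,
    make_feature_annotation,
    simulate_study,
)

__all__ = [
    "null_fdr_calibration",
    "contrast_recovery",
    "pca_template_separation",
    "pls_null_calibration",
    "pls_signal_validity",
    "selection_operating_characteristics",
    "congruence_recovery",
    "disjoint_effects_sharing",
    "chain_match_recovery",
]

LN2 = float(np.log(2.0))


def _seeds(root: int, n: int) -> list[int]:
    rng = np.random.default_rng(root)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

def null_fdr_calibration(n_reps: int = 100, n_features: int = 500,
                         alpha: float = 0.05, seed: int = 0) -> dict:
    """Realised false-discovery proportion on fully null studies.

    Every vs-SAL rejection on a no-effect generator is a false discovery,
    so the per-family FDP is 1 whenever any feature is rejected. BH should
    keep the mean FDP at or below alpha.
    """
    fdps = []
    for s in _seeds(seed, n_reps):
        fm, _, _ = simulate_study(n_features=n_features, seed=s,
                                  effect=EffectSpec.null())
        con = InteractionMixedLM(fm).fit().contrasts("vs_sal")
        for _, fam in con.groupby("pair"):
            r = int((fam["q"] < alpha).sum())
            fdps.append(1.0 if r > 0 else 0.0)
    fdps = np.asarray(fdps)
    mc_se = float(fdps.std(ddof=1) / np.sqrt(len(fdps))) if len(fdps) > 1 else 0.0
    return {"mean_fdp": float(fdps.mean()), "mc_se": mc_se,
            "bound": alpha + 2 * mc_se, "n_families": len(fdps)}


def contrast_recovery(n_features: int = 1000, delta_log2: float = 1.0,
                      seed: int = 0) -> dict:
    """Bias and 95% CI coverage for an injected VLCD effect."""
    idx = [f"PF{i:04d}" for i in range(n_features)]
    delta = pd.DataFrame({"VLCD": delta_log2}, index=idx)
    fm, _, _ = simulate_study(
        n_features=n_features, seed=seed,
        effect=EffectSpec(delta=delta, sal_drift_sd=0.0))
    res = InteractionMixedLM(fm).fit()
    con = res.contrasts("vs_sal")
    con = con[con["pair"] == "VLCD_vs_SAL"]
    tcrit = stats.t.ppf(0.975, con["df"].iloc[0])
    lo = (con["estimate"] - tcrit * con["se"]) / LN2
    hi = (con["estimate"] + tcrit * con["se"]) / LN2
    cover = float(((lo <= delta_log2) & (delta_log2 <= hi)).mean())
    bias = float((con["estimate_log2"] - delta_log2).mean())
    return {"bias": bias, "coverage": cover, "n_features": n_features}


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_template_separation(n_seeds: int = 100, n_features: int = 500,
                            seed: int = 0, p_threshold: float = 0.01) -> dict:
    """How often VLCD and RYGB separate from SAL on PC1 under template effects.

    Caloric-restriction template signs with unit-log2 magnitudes; the
    separation call uses the pairwise Welch p on the first component.
    """
    hits = 0
    for s in _seeds(seed, n_seeds):
        features = make_feature_annotation(n_features, seed=s)
        signs = caloric_restriction_template(features)
        fm, _, _ = simulate_study(
            features=features, seed=s,
            effect=EffectSpec(signs=signs, effect_sizes=(1.0,)))
        fc = compute_fold_changes(fm)
        tab = FoldChangePCA(fc, n_components=2).fit().group_tests()
        pc1 = tab[tab["component"] == "PC1"].set_index("test")
        ok = (pc1.loc["SAL_vs_VLCD", "p"] < p_threshold
              and pc1.loc["SAL_vs_RYGB", "p"] < p_threshold)
        hits += int(ok)
    return {"separation_rate": hits / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------

def _latent_xy(rng, n: int = 60, p: int = 100, n_informative: int = 30,
               true_r2: float = 0.9):
    """Latent-factor design: informative columns load on t, y = t + noise."""
    t = rng.normal(size=n)
    X = rng.normal(size=(n, p))
    X[:, :n_informative] += np.outer(t, np.ones(n_informative))
    noise_sd = np.sqrt((1.0 - true_r2) / true_r2)
    y = t + noise_sd * rng.normal(size=n)
    return X, y


def pls_null_calibration(n_q2_reps: int = 200, n_validity_runs: int = 100,
                         n: int = 60, p: int = 100, B: int = 200,
                         n_components: int = 2, seed: int = 0) -> dict:
    """Mean CV Q2 and validity rate when y is independent of X."""
    seeds = _seeds(seed, max(n_q2_reps, n_validity_runs))
    q2s = []
    for s in seeds[:n_q2_reps]:
        rng = np.random.default_rng(s)
        X, y = rng.normal(size=(n, p)), rng.normal(size=n)
        q2s.append(q2y_cv(X, y, n_components, folds=7, seed=s))
    n_valid = 0
    for s in seeds[:n_validity_runs]:
        rng = np.random.default_rng(s + 1)
        X = pd.DataFrame(rng.normal(size=(n, p)))
        y = pd.Series(rng.normal(size=n))
        res = PLSRegression1(X, y, n_components=n_components, seed=s).fit()
        rep = res.permutation_test(B=B, seed=s)
        n_valid += int(rep.valid)
    return {"mean_null_q2": float(np.mean(q2s)),
            "null_validity_rate": n_valid / n_validity_runs,
            "n_q2_reps": n_q2_reps, "n_validity_runs": n_validity_runs}


def pls_signal_validity(n_runs: int = 100, n: int = 60, p: int = 100,
                        true_r2: float = 0.9, B: int = 200,
                        n_components: int = 2, seed: int = 0) -> dict:
    """Q2 and validity pass rates under a strong latent linear signal."""
    q2_pass = valid = 0
    for s in _seeds(seed, n_runs):
        rng = np.random.default_rng(s)
        X, y = _latent_xy(rng, n=n, p=p, true_r2=true_r2)
        res = PLSRegression1(pd.DataFrame(X), pd.Series(y),
                             n_components=n_components, seed=s).fit()
        q2_pass += int(res.q2y > 0.15)
        rep = res.permutation_test(B=B, seed=s)
        valid += int(rep.valid)
    return {"q2_pass_rate": q2_pass / n_runs, "validity_rate": valid / n_runs,
            "n_runs": n_runs}


def selection_operating_characteristics(
    n_seeds: int = 100, n_features: int = 500, n_informative: int = 200,
    slope: float = 0.3, B: int = 200, seed: int = 0,
) -> dict:
    """Sensitivity / null selection rate of empirical weight selection.

    60 subjects (15 per arm), no treatment effects; the informative features
    are linked to the weight delta (a latent clinical response every linked
    feature tracks), and PLS models weight on per-subject fold changes.
    """
    n_per = {g: 15 for g in GROUPS}
    informative = [f"PF{i:04d}" for i in range(n_informative)]
    link = {f: ("weight", slope) for f in informative}
    sens, null_rate, n_valid = [], [], 0
    for s in _seeds(seed, n_seeds):
        fm, clin, _ = simulate_study(
            n_per_group=n_per, n_features=n_features, seed=s,
            effect=EffectSpec.null(), clinical_link=link)
        fc = compute_fold_changes(fm)
        y = clin.factor("weight").loc[fc.subjects]
        res = PLSRegression1(fc.values, y, n_components=1,
                             groups=fc.groups, seed=s).fit()
        rep = res.permutation_test(B=B, seed=s)
        if not rep.valid:
            continue
        n_valid += 1
        t = rep.feature_table
        is_inf = t.index.isin(informative)
        hit = t["empirical_p"] < 0.05
        sens.append(float(hit[is_inf].mean()))
        null_rate.append(float(hit[~is_inf].mean()))
    return {"sensitivity": float(np.mean(sens)),
            "null_selection_rate": float(np.mean(null_rate)),
            "valid_runs": n_valid, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# congruence
# ---------------------------------------------------------------------------

def congruence_recovery(n_seeds: int = 100, rho: float = 0.9,
                        n_features: int = 500, seed: int = 0) -> dict:
    """Estimated VLCD-RYGB mean-fold-change correlation vs the target rho."""
    rs = []
    for s in _seeds(seed, n_seeds):
        fm, _, _ = simulate_study(
            n_features=n_features, seed=s,
            effect=EffectSpec(congruence_rho=rho, effect_sizes=(1.0,)))
        fc = compute_fold_changes(fm)
        con = InteractionMixedLM(fm).fit().contrasts("vs_sal")
        rep = pairwise_congruence(mean_fold_changes(fc), con)
        rs.append(float(rep.pair_r.set_index("pair").loc["VLCD_vs_RYGB", "r"]))
    return {"mean_r": float(np.mean(rs)), "sd_r": float(np.std(rs, ddof=1)),
            "target_rho": rho, "n_seeds": n_seeds}


def disjoint_effects_sharing(n_seeds: int = 100, n_features: int = 500,
                             n_unique: int = 10, seed: int = 0) -> dict:
    """How often the 'shared' category stays empty under disjoint effects."""
    empty = 0
    idx = [f"PF{i:04d}" for i in range(n_features)]
    for s in _seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        delta = pd.DataFrame(0.0, index=idx, columns=["VLCD", "RYGB"])
        pick = rng.choice(n_features, size=2 * n_unique, replace=False)
        delta.iloc[pick[:n_unique], 0] = rng.choice([-1.0, 1.0], n_unique)
        delta.iloc[pick[n_unique:], 1] = rng.choice([-1.0, 1.0], n_unique)
        fm, _, _ = simulate_study(
            n_features=n_features, seed=s,
            effect=EffectSpec(delta=delta, sal_drift_sd=0.0))
        fc = compute_fold_changes(fm)
        con = InteractionMixedLM(fm).fit().contrasts("vs_sal")
        rep = pairwise_congruence(mean_fold_changes(fc), con)
        empty += int((rep.categories == "shared").sum() == 0)
    return {"shared_empty_rate": empty / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# chain matching
# ---------------------------------------------------------------------------

def chain_match_recovery(seed: int = 0, noise_sd: float = 0.1) -> dict:
    """Recover constructed anti-correlated FA / (lyso)phospholipid effects.

    Each fatty acid gets a random per-arm effect; its matched partners
    (PC on sn-2, LPC/LPE on their single chain) get minus that effect plus
    small noise. The per-class chain-match correlation should approach -1.
    """
    rng = np.random.default_rng(seed)
    chains = [(14, 0), (16, 0), (16, 1), (18, 1), (18, 2), (20, 4), (22, 6)]
    rows, delta_rows = [], {}
    for i, (c, d) in enumerate(chains):
        fa = f"fa{i}"
        eff = rng.normal(0.0, 1.0, size=4)
        rows.append((fa, "lipidRPCpos", "fatty acid", f"FA({c}:{d})", True))
        delta_rows[fa] = eff
        for j, name_cls in enumerate([
            (f"PC(16:0/{c}:{d})", "phosphatidylcholine"),
            (f"LPC({c}:{d})", "lysophospholipid"),
            (f"LPE({c}:{d})", "lysophospholipid"),
        ]):
            pid = f"p{i}_{j}"
            rows.append((pid, "lipidRPCneg", name_cls[1], name_cls[0], True))
            delta_rows[pid] = -eff + rng.normal(0.0, noise_sd, size=4)
    features = pd.DataFrame(
        rows, columns=["feature_id", "platform", "metabolite_class", "name",
                       "annotated"]).set_index("feature_id")
    from .lipids import parse_lipid_name
    features["lipid"] = [parse_lipid_name(n) for n in features["name"]]
    delta = pd.DataFrame(delta_rows, index=list(GROUPS)).T
    fm, _, _ = simulate_study(
        features=features, seed=seed,
        effect=EffectSpec(delta=delta, sal_drift_sd=0.0),
        noise=NoiseSpec(sigma_subject=0.3, sigma_resid=0.05))
    means = mean_fold_changes(compute_fold_changes(fm))
    matches = build_matches(features)
    _, class_r = match_covariation(matches, means)
    out = {row["partner_class"]: float(row["r"])
           for _, row in class_r.iterrows()}
    out["n_matches"] = int(len(matches))
    return out
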