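"""Acyl-chain matching between free fatty acids and complex lipids.

During caloric restriction, fatty acids mobilised from membrane
(lyso)phospholipids and esterified into acylcarnitines should co-vary with
their donor/acceptor species of identical chain composition. This module
matches each free fatty acid FA(c:d) to:

* acylcarnitines CAR(c:d) on the identical single chain (``same_chain``),
* phosphatidylcholines PC(sn1/sn2) whose sn-2 chain equals (c:d) (``sn2``),
  with different sn-1 chains kept as distinct partners,
* lysophospholipids LPC/LPE/LPI/LPA(c:d) on their single chain
  (``same_chain``),
* ceramides and sphingomyelins on the N-acyl chain (``n_acyl``).

Matching requires exact (carbons, double_bonds) equality; sum-composition
names (e.g. TG(48:1)) lack chain resolution and are skipped. Each match
contributes one row per intervention to the co-variation analysis, and
Pearson r is computed per partner class (and per lysophospholipid subclass)
over the pooled rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lipids import (
    LYSOPHOSPHOLIPID_CLASSES,
    SPHINGOLIPID_CLASSES,
    LipidDescriptor,
    VERY_LONG_CHAIN_CARBONS,
)
from .congruence import _pearson

__all__ = ["build_matches", "match_covariation"]

PARTNER_CLASSES = ("CAR", "PC") + LYSOPHOSPHOLIPID_CLASSES + SPHINGOLIPID_CLASSES


def _matched_chain(lip: LipidDescriptor) -> tuple[tuple[int, int], str] | None:
    """Chain a partner lipid exposes for FA matching, and the rule used."""
    if lip.lipid_class == "CAR":
        return lip.chains[0].key, "same_chain"
    if lip.lipid_class in LYSOPHOSPHOLIPID_CLASSES:
        return lip.chains[0].key, "same_chain"
    if lip.lipid_class == "PC":
        if not lip.sn_resolved or len(lip.chains) < 2:
            return None  # ambiguous sn positions are excluded, not guessed
        return lip.chains[1].key, "sn2"
    if lip.lipid_class in SPHINGOLIPID_CLASSES:
        if not lip.sn_resolved or len(lip.chains) != 2:
            return None
        return lip.chains[1].key, "n_acyl"
    return None


def build_matches(features: pd.DataFrame) -> pd.DataFrame:
    """Match free fatty acids to complex-lipid partners by exact chain.

    Parameters
    ----------
    features
        Feature-annotation table with a ``lipid`` column of parsed
        descriptors (``None`` for non-lipids).

    Returns
    -------
    DataFrame with one row per (fatty acid, partner) pair: fatty_acid_feature,
    partner_feature, partner_class, matched_carbons, matched_double_bonds,
    match_rule, very_long_chain. Deterministic and independent of input
    order (rows sorted on the pair key).
    """
    fas = []
    partners = []
    for fid, row in features.iterrows():
        lip = row.get("lipid")
        if not isinstance(lip, LipidDescriptor):
            continue
        if lip.lipid_class == "FA":
            fas.append((fid, lip.chains[0].key))
        elif lip.lipid_class in PARTNER_CLASSES:
            mc = _matched_chain(lip)
            if mc is not None:
                partners.append((fid, lip.lipid_class, *mc))
    rows = []
    for fa_id, chain in fas:
        for p_id, p_cls, p_chain, rule in partners:
            if p_chain == chain:
                rows.append({
                    "fatty_acid_feature": fa_id,
                    "partner_feature": p_id,
                    "partner_class": p_cls,
                    "matched_carbons": chain[0],
                    "matched_double_bonds": chain[1],
                    "match_rule": rule,
                    "very_long_chain": chain[0] >= VERY_LONG_CHAIN_CARBONS,
                })
    out = pd.DataFrame(rows, columns=[
        "fatty_acid_feature", "partner_feature", "partner_class",
        "matched_carbons", "matched_double_bonds", "match_rule",
        "very_long_chain",
    ])
    return out.sort_values(["fatty_acid_feature", "partner_feature"],
                           ignore_index=True)


def match_covariation(
    matches: pd.DataFrame,
    means: pd.DataFrame,
    pool_lyso: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Co-variation of intervention effects across matched chains.

    Each (match x intervention) contributes one point: x = mean log2 fold
    change of the fatty acid, y = that of the partner, for that arm.
    Pearson r is computed per partner class over the pooled points; with
    ``pool_lyso`` an additional pooled "lyso" class combines the
    lysophospholipid subclasses. Classes with fewer than 3 points get
    r = NA.

    Returns (points, class_r): the long scatter table and the per-class
    correlation table.
    """
    wide = means.pivot(index="feature_id", columns="group", values="mean")
    rows = []
    for _, mrow in matches.iterrows():
        fa, pf = mrow["fatty_acid_feature"], mrow["partner_feature"]
        if fa not in wide.index or pf not in wide.index:
            continue
        for g in wide.columns:
            rows.append({
                "fatty_acid_feature": fa,
                "partner_feature": pf,
                "partner_class": mrow["partner_class"],
                "group": g,
                "fa_mean_log2fc": wide.loc[fa, g],
                "partner_mean_log2fc": wide.loc[pf, g],
                "very_long_chain": mrow["very_long_chain"],
            })
    points = pd.DataFrame(rows, columns=[
        "fatty_acid_feature", "partner_feature", "partner_class", "group",
        "fa_mean_log2fc", "partner_mean_log2fc", "very_long_chain",
    ])

    def _cls_r(sub: pd.DataFrame) -> tuple[float, float]:
        return _pearson(sub["fa_mean_log2fc"].to_numpy(dtype=float),
                        sub["partner_mean_log2fc"].to_numpy(dtype=float))

    crows = []
    for cls, sub in points.groupby("partner_class"):
        r, p = _cls_r(sub)
        crows.append((cls, r, p, len(sub)))
    if pool_lyso:
        sub = points[points["partner_class"].isin(LYSOPHOSPHOLIPID_CLASSES)]
        if len(sub):
            r, p = _cls_r(sub)
            crows.append(("lyso", r, p, len(sub)))
    class_r = pd.DataFrame(crows, columns=["partner_class", "r", "p", "n_points"])
    return points, class_r.sort_values("partner_class", ignore_index=True)
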