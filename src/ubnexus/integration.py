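"""Evidence integration: combine the three streams into substrate nominations.

A candidate substrate must (i) lose a ubiquitylation site when the
ligase is deleted, (ii) be detected in the endogenous ligase complex
(significance-box interactor), and (iii) show a ligase-context-dependent
fitness effect in the screen.  The nominated set is exactly the triple
intersection; a composite z-score ranks nominations for reporting.
"""
from __future__ import annotations

import numpy as np
import pandas as pd


def build_profiles(lost_ub: pd.DataFrame,
                   interactions: pd.DataFrame,
                   screen: pd.DataFrame,
                   id_map: pd.DataFrame | None = None) -> pd.DataFrame:
    """Outer-join the three evidence streams into per-protein profiles.

    Inputs are the stage outputs: ``lost_ub`` (protein_id, lost_ub,
    min_site_log2fc), ``interactions`` (protein_id, in_box, G, p_value),
    ``screen`` (gene_id, classification, q_value, mean_paired_diff).
    ``id_map`` (gene_id, protein_id) harmonizes the screen's gene ids;
    identity mapping by default.  Unmapped gene ids are kept with an
    ``unmapped`` flag, never dropped.  Absent evidence is False, with
    per-stream ``seen_*`` indicators recording missingness.
    """
    ub = lost_ub[["protein_id", "lost_ub", "min_site_log2fc"]].copy()
    ub["seen_ub"] = True

    ip = interactions[["protein_id", "in_box", "G", "p_value"]].rename(
        columns={"p_value": "ip_p_value"}).copy()
    ip["seen_ip"] = True

    sc = screen[["gene_id", "classification", "q_value", "mean_paired_diff"]].rename(
        columns={"q_value": "screen_q_value"}).copy()
    if id_map is not None:
        mapping = id_map.set_index("gene_id")["protein_id"]
        sc["protein_id"] = sc["gene_id"].map(mapping)
        sc["unmapped"] = sc["protein_id"].isna()
        sc.loc[sc["unmapped"], "protein_id"] = sc.loc[sc["unmapped"], "gene_id"]
    else:
        sc["protein_id"] = sc["gene_id"]
        sc["unmapped"] = False
    sc["screen_dependent"] = sc["classification"] != "none"
    sc["seen_screen"] = True
    sc = sc.drop(columns=["gene_id"])

    prof = ub.merge(ip, on="protein_id", how="outer").merge(
        sc, on="protein_id", how="outer")
    for col in ("lost_ub", "in_box", "screen_dependent",
                "seen_ub", "seen_ip", "seen_screen", "unmapped"):
        prof[col] = prof[col].astype("boolean").fillna(False).astype(bool)
    prof["classification"] = prof["classification"].fillna("none")
    return prof.sort_values("protein_id").reset_index(drop=True)


def _zscore(x: pd.Series) -> pd.Series:
    v = x.astype(float)
    mu = v.mean(skipna=True)
    sd = v.std(skipna=True, ddof=0)
    if not np.isfinite(sd) or sd == 0:
        return pd.Series(0.0, index=x.index)
    return ((v - mu) / sd).fillna(0.0)


def nominate(profiles: pd.DataFrame) -> pd.DataFrame:
    """Rank nominations: nominated iff all three evidence booleans hold.

    The rank score is a composite of stream z-scores — z(-min site
    log2FC), z(G), z(|mean paired difference|) — an artifact-level
    ordering aid on top of the intersection criterion.
    """
    out = profiles.copy()
    out["nominated"] = (out["lost_ub"] & out["in_box"] & out["screen_dependent"])
    score = (_zscore(-out["min_site_log2fc"])
             + _zscore(out["G"])
             + _zscore(out["mean_paired_diff"].abs()))
    out["rank_score"] = score
    return out.sort_values(["nominated", "rank_score"],
                           ascending=[False, False]).reset_index(drop=True)
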