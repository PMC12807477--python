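"""Differential diGly-site analysis: per-site log2FC and lost-Ub flags.

A ubiquitylated peptide's intensity in the ligase-knockout versus
wild-type cells tells whether the site depends on the ligase: a strong
KO/WT decrease (log2FC at or below -threshold) marks a lost
ubiquitylation event and nominates the protein as a candidate substrate.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 0.5   # |log2FC| cutoff for differential sites
DEFAULT_PSEUDOCOUNT = 1.0  # intensity units, guards all-zero rows


class UndefinedRatioError(ValueError):
    """A fold change could not be formed (zero mean with zero pseudocount)."""


def site_log2fc(table: pd.DataFrame,
                ko_cols: Sequence[str],
                wt_cols: Sequence[str],
                pseudocount: float = DEFAULT_PSEUDOCOUNT,
                threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Per-site log2 fold change, KO vs WT.

    Replicates are collapsed by the arithmetic mean of intensities, then
    log2FC = log2((mean_KO + pc) / (mean_WT + pc)).  Returns one row per
    site with ``passes_filter`` (|log2FC| >= threshold) and ``lost_ub``
    (log2FC <= -threshold) flags.
    """
    if len(ko_cols) == 0 or len(wt_cols) == 0:
        raise ValueError("both condition groups must be present")
    missing = [c for c in list(ko_cols) + list(wt_cols) if c not in table.columns]
    if missing:
        raise ValueError(f"missing intensity columns: {missing}")
    ko = table[list(ko_cols)].to_numpy(dtype=float)
    wt = table[list(wt_cols)].to_numpy(dtype=float)
    if (ko < 0).any() or (wt < 0).any() or not (np.isfinite(ko).all()
                                                and np.isfinite(wt).all()):
        raise ValueError("intensities must be finite and non-negative")
    mean_ko = ko.mean(axis=1) + pseudocount
    mean_wt = wt.mean(axis=1) + pseudocount
    if (mean_ko <= 0).any() or (mean_wt <= 0).any():
        bad = table.loc[(mean_ko <= 0) | (mean_wt <= 0), "peptide_key"].tolist()
        raise UndefinedRatioError(
            f"zero mean intensity with pseudocount {pseudocount}: {bad[:5]}")
    lfc = np.log2(mean_ko) - np.log2(mean_wt)
    out = table[["protein_id", "site_position", "peptide_key"]].copy()
    out["log2fc"] = lfc
    out["passes_filter"] = np.abs(lfc) >= threshold
    out["lost_ub"] = lfc <= -threshold
    return out


def flag_lost_ub(site_results: pd.DataFrame,
                 threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Per-protein lost-ubiquitylation flag.

    A protein is flagged iff at least one of its sites has
    log2FC <= -threshold.  Also reports the most negative site log2FC as
    the protein's supporting effect size.
    """
    grouped = site_results.groupby("protein_id")["log2fc"]
    out = pd.DataFrame({
        "min_site_log2fc": grouped.min(),
        "n_sites": grouped.size(),
    })
    out["lost_ub"] = out["min_site_log2fc"] <= -threshold
    return out.reset_index()
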