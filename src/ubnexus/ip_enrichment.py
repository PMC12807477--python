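"""Bait-specific interactor calling from IP vs IgG spectral counts.

For each protein the observed spectral counts in the bait IP and the IgG
control are compared with a likelihood-ratio (G) test against the
expectation that the protein occupies the same fraction of both runs'
sampling depth.  Proteins inside the significance box (p below alpha and
fold enrichment above the cutoff) are called interactors, and a
pre-scored edge table restricted to those calls yields the confidence-
filtered interaction network.
"""
from __future__ import annotations

from typing import Iterable

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

DEFAULT_ALPHA = 0.05
DEFAULT_FOLD = 1.5
DEFAULT_PSEUDOCOUNT = 0.5   # fold enrichment only; never applied to G
DEFAULT_CONFIDENCE = 0.7    # medium-confidence network cutoff


def g_test(c_ip, c_igg, t_ip, t_igg):
    """Spectral-count G test of equal IP/IgG sampling proportions.

    With n = c_ip + c_igg and expected counts e_i = T_i * n / (T_ip + T_igg),
    G = 2 * sum_i c_i * ln(c_i / e_i) (zero counts contribute zero), and p
    comes from the chi-square distribution with 1 df.  Expected counts are
    formed from the run totals (per-run sampling depth), not from 2x2 row
    marginals, so unequal depths are handled directly.  Vectorized.
    """
    c_ip = np.asarray(c_ip, dtype=float)
    c_igg = np.asarray(c_igg, dtype=float)
    t_ip = float(t_ip)
    t_igg = float(t_igg)
    if t_ip <= 0 or t_igg <= 0:
        raise ValueError("run totals must be positive")
    if (c_ip < 0).any() or (c_igg < 0).any():
        raise ValueError("counts must be non-negative")
    if (c_ip > t_ip).any() or (c_igg > t_igg).any():
        raise ValueError("a count exceeds its run total")
    n = c_ip + c_igg
    grand = t_ip + t_igg
    with np.errstate(divide="ignore", invalid="ignore"):
        e_ip = t_ip * n / grand
        e_igg = t_igg * n / grand
        term_ip = np.where(c_ip > 0, c_ip * np.log(np.where(c_ip > 0, c_ip, 1.0) / e_ip), 0.0)
        term_igg = np.where(c_igg > 0, c_igg * np.log(np.where(c_igg > 0, c_igg, 1.0) / e_igg), 0.0)
    g = 2.0 * (term_ip + term_igg)
    g = np.where(n > 0, np.maximum(g, 0.0), 0.0)
    p = sps.chi2.sf(g, df=1)
    p = np.where(n > 0, p, 1.0)
    if np.isscalar(c_ip) or g.ndim == 0:
        return float(g), float(p)
    return g, p


def fold_enrichment(c_ip, c_igg, t_ip, t_igg,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Depth-normalized IP/IgG abundance ratio with a zero-guard pseudocount:
    ((c_ip + pc) / T_ip) / ((c_igg + pc) / T_igg)."""
    c_ip = np.asarray(c_ip, dtype=float)
    c_igg = np.asarray(c_igg, dtype=float)
    if t_ip <= 0 or t_igg <= 0:
        raise ValueError("run totals must be positive")
    fe = ((c_ip + pseudocount) / t_ip) / ((c_igg + pseudocount) / t_igg)
    if fe.ndim == 0:
        return float(fe)
    return fe


def call_interactors(table: pd.DataFrame,
                     alpha: float = DEFAULT_ALPHA,
                     fold_cutoff: float = DEFAULT_FOLD,
                     pseudocount: float = DEFAULT_PSEUDOCOUNT,
                     adjust: bool = False) -> pd.DataFrame:
    """Score every protein and mark the significance-box members.

    ``table`` needs columns protein_id, count_ip, count_igg; run totals
    are computed from the column sums.  ``in_box`` means p < alpha and
    fold enrichment > fold_cutoff (BH-adjusted p instead when
    ``adjust``).  Result is sorted by G descending.
    """
    counts_ip = table["count_ip"].to_numpy()
    counts_igg = table["count_igg"].to_numpy()
    if not (np.equal(np.mod(counts_ip, 1), 0).all()
            and np.equal(np.mod(counts_igg, 1), 0).all()):
        raise ValueError("spectral counts must be integers")
    t_ip = int(counts_ip.sum())
    t_igg = int(counts_igg.sum())
    if t_ip + t_igg == 0:
        raise ValueError("zero grand total")
    g, p = g_test(counts_ip, counts_igg, t_ip, t_igg)
    fe = fold_enrichment(counts_ip, counts_igg, t_ip, t_igg, pseudocount)
    out = table[["protein_id"]].copy()
    out["count_ip"] = counts_ip
    out["count_igg"] = counts_igg
    out["G"] = g
    out["p_value"] = p
    out["q_value"] = bh_adjust(p)
    out["fold_enrichment"] = fe
    crit_p = out["q_value"] if adjust else out["p_value"]
    out["in_box"] = (crit_p < alpha) & (out["fold_enrichment"] > fold_cutoff)
    return out.sort_values("G", ascending=False).reset_index(drop=True)


def assemble_network(edge_table: pd.DataFrame,
                     confidence_cutoff: float = DEFAULT_CONFIDENCE,
                     node_whitelist: Iterable[str] | None = None) -> nx.Graph:
    """Confidence-filtered undirected network over the called interactors.

    Edges below the cutoff and self-loops are dropped; when a whitelist
    (the in-box proteins plus the bait) is given, only those nodes are
    kept — all of them, including isolated ones, mirroring an
    input-nodes-only network view.
    """
    g = nx.Graph()
    wl = set(node_whitelist) if node_whitelist is not None else None
    if wl is not None:
        g.add_nodes_from(sorted(wl))
    for a, b, conf in edge_table[["node_a", "node_b", "confidence"]].itertuples(index=False):
        if a == b or conf < confidence_cutoff:
            continue
        if wl is not None and (a not in wl or b not in wl):
            continue
        g.add_edge(a, b, confidence=float(conf))
    return g
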