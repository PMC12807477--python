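"""Exon-inclusion (PSI) analysis from junction counts.

PSI = I / (I + S) per sample (optionally length-normalized); group
differences are tested with a likelihood-ratio test on binomial
inclusion proportions pooled within each group; significant events pass
the joint filter FDR < 0.05, p < 0.05 and |delta-PSI| > 0.15; samples
are grouped by the expression quartiles of a chosen gene.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

DEFAULT_FDR = 0.05
DEFAULT_P = 0.05
DEFAULT_DPSI = 0.15


@dataclass
class SpliceEventTable:
    """Junction counts per event: meta (gene, event_type, form lengths),
    inclusion and skipping count matrices (events x samples)."""

    meta: pd.DataFrame
    inclusion: pd.DataFrame
    skipping: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.inclusion.index.equals(self.meta.index)
                and self.skipping.index.equals(self.meta.index)):
            raise ValueError("count matrices must share the meta index")
        if not self.inclusion.columns.equals(self.skipping.columns):
            raise ValueError("inclusion/skipping must share sample columns")
        if (self.inclusion.to_numpy() < 0).any() or (self.skipping.to_numpy() < 0).any():
            raise ValueError("junction counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.inclusion.columns)


def compute_psi(inclusion, skipping,
                len_inclusion=None, len_skipping=None,
                length_normalize: bool = False):
    """Percent spliced in.  Undefined (NaN) iff I + S = 0.

    Default PSI = I/(I+S); with ``length_normalize``,
    PSI = (I/lI) / ((I/lI) + (S/lS)).
    """
    i = np.asarray(inclusion, dtype=float)
    s = np.asarray(skipping, dtype=float)
    if length_normalize:
        if len_inclusion is None or len_skipping is None:
            raise ValueError("length normalization requires both form lengths")
        i = i / np.asarray(len_inclusion, dtype=float)
        s = s / np.asarray(len_skipping, dtype=float)
    total = i + s
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total > 0, i / np.where(total > 0, total, 1.0), np.nan)
    if psi.ndim == 0:
        return float(psi) if total > 0 else float("nan")
    return psi


def _binomial_lrt(i1: float, s1: float, i2: float, s2: float) -> tuple[float, float]:
    """LRT of equal inclusion proportion between two pooled groups."""
    def ll(i: float, s: float, p: float) -> float:
        out = 0.0
        if i > 0:
            out += i * np.log(p)
        if s > 0:
            out += s * np.log(1.0 - p)
        return out

    n1, n2 = i1 + s1, i2 + s2
    p1, p2 = i1 / n1, i2 / n2
    p0 = (i1 + i2) / (n1 + n2)
    g = 2.0 * (ll(i1, s1, p1) + ll(i2, s2, p2) - ll(i1, s1, p0) - ll(i2, s2, p0))
    g = max(g, 0.0)
    return g, float(sps.chi2.sf(g, df=1))


def event_test(table: SpliceEventTable,
               group1: Sequence[str],
               group2: Sequence[str],
               fdr_cutoff: float = DEFAULT_FDR,
               p_cutoff: float = DEFAULT_P,
               dpsi_cutoff: float = DEFAULT_DPSI,
               length_normalize: bool = False) -> pd.DataFrame:
    """Per-event group comparison of inclusion levels.

    Counts are pooled within each group for a binomial LRT (H0: shared
    inclusion proportion); delta-PSI is the difference of group mean
    per-sample PSIs; q is BH across tested events.  Events with zero
    coverage throughout a group are skipped with a reason.  ``passes``
    applies the joint filter (q < fdr, p < p_cutoff, |dPSI| > dpsi).
    """
    g1 = list(group1)
    g2 = list(group2)
    missing = [c for c in g1 + g2 if c not in table.inclusion.columns]
    if missing:
        raise ValueError(f"unknown samples: {missing}")
    li = table.meta["len_inclusion"].to_numpy()[:, None]
    ls = table.meta["len_skipping"].to_numpy()[:, None]
    psi = compute_psi(table.inclusion.to_numpy(), table.skipping.to_numpy(),
                      li, ls, length_normalize=length_normalize)
    psi = pd.DataFrame(psi, index=table.meta.index, columns=table.samples)

    i1 = table.inclusion[g1].sum(axis=1).to_numpy(dtype=float)
    s1 = table.skipping[g1].sum(axis=1).to_numpy(dtype=float)
    i2 = table.inclusion[g2].sum(axis=1).to_numpy(dtype=float)
    s2 = table.skipping[g2].sum(axis=1).to_numpy(dtype=float)
    testable = (i1 + s1 > 0) & (i2 + s2 > 0)

    stat = np.full(len(psi), np.nan)
    p = np.full(len(psi), np.nan)
    for k in np.flatnonzero(testable):
        stat[k], p[k] = _binomial_lrt(i1[k], s1[k], i2[k], s2[k])

    out = table.meta[["gene", "event_type"]].copy()
    out["psi_group1"] = psi[g1].mean(axis=1, skipna=True)
    out["psi_group2"] = psi[g2].mean(axis=1, skipna=True)
    out["delta_psi"] = out["psi_group1"] - out["psi_group2"]
    out["lr_statistic"] = stat
    out["p_value"] = p
    out["q_value"] = bh_adjust(p)
    out["skipped_reason"] = np.where(testable, "", "no_coverage_in_group")
    out["passes"] = ((out["q_value"] < fdr_cutoff)
                     & (out["p_value"] < p_cutoff)
                     & (out["delta_psi"].abs() > dpsi_cutoff)).fillna(False)
    return out


def filter_events(results: pd.DataFrame) -> tuple[set, pd.Series]:
    """(passing event ids, passing counts per event type)."""
    passing = results[results["passes"]]
    ids = set(passing.index)
    counts = passing.groupby("event_type").size()
    counts = counts.reindex(sorted(results["event_type"].unique()), fill_value=0)
    return ids, counts


@dataclass
class ExpressionQuartileGroups:
    high: list[str]      # >= 75th percentile of expression
    low: list[str]       # <= 25th percentile
    q25: float
    q75: float
    degenerate: bool


def quartile_groups(expression: pd.Series) -> ExpressionQuartileGroups:
    """Split samples by one gene's expression quartiles.

    Upper-quartile samples (>= Q3) are the high-expression group,
    lower-quartile (<= Q1) the low group; the middle half is unassigned.
    Boundaries are inclusive; an all-tied vector is degenerate and
    yields empty groups.
    """
    x = expression.dropna()
    if len(x) < 4:
        raise ValueError("need >= 4 samples for quartile grouping")
    q25, q75 = np.percentile(x.to_numpy(dtype=float), [25, 75])
    if q75 <= q25:
        return ExpressionQuartileGroups(high=[], low=[], q25=float(q25),
                                        q75=float(q75), degenerate=True)
    high = x.index[x >= q75].tolist()
    low = x.index[x <= q25].tolist()
    return ExpressionQuartileGroups(high=high, low=low, q25=float(q25),
                                    q75=float(q75), degenerate=False)
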