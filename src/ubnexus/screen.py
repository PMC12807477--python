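"""Guide-level CRISPR screen analysis and the per-gene context test.

Each gene is represented by a fixed set of guides counted at day 0 and
day 10 in two backgrounds (sgCTRL and sgFBXO11).  Guide abundances are
depth-normalized (CPM), summarized as log2 day10/day0 fold changes
averaged over replicates, and each gene's matched guide fold changes are
compared between the two contexts with a two-tailed paired t test.  A
significant, signed difference classifies the gene as selectively
enriched or depleted in one context.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust
from .synthetic import SCREEN_CONTEXTS, SCREEN_TIMEPOINTS, screen_column

DEFAULT_ALPHA = 0.05
DEFAULT_PSEUDOCOUNT = 1.0   # CPM units

CLASSES = ("enriched_sgCTRL", "enriched_sgFBXO11",
           "depleted_sgCTRL", "depleted_sgFBXO11", "none")


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale every sample column to one million total counts."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero-total sample column(s): {bad}")
    return counts * 1e6 / totals


def guide_log2fc(cpm: pd.DataFrame,
                 day10_cols: Sequence[str],
                 day0_cols: Sequence[str],
                 pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.Series:
    """Per-guide log2 day10/day0 fold change, averaged over matched replicates.

    ``day10_cols[i]`` is paired with ``day0_cols[i]``; each replicate's FC is
    log2((cpm10 + pc) / (cpm0 + pc)) and replicates are averaged at the FC
    level.
    """
    if len(day10_cols) != len(day0_cols) or len(day0_cols) == 0:
        raise ValueError("day10/day0 replicate columns must be matched and non-empty")
    fcs = []
    for c10, c0 in zip(day10_cols, day0_cols):
        fcs.append(np.log2(cpm[c10] + pseudocount) - np.log2(cpm[c0] + pseudocount))
    return pd.concat(fcs, axis=1).mean(axis=1)


@dataclass
class _GeneRow:
    gene_id: str
    n_guides: int
    median_fc_sgCTRL: float
    median_fc_sgFBXO11: float
    mean_paired_diff: float
    t_statistic: float
    p_value: float
    degenerate: bool


def _paired_test(fc_ctrl: np.ndarray, fc_fbx: np.ndarray) -> tuple[float, float, bool]:
    d = fc_fbx - fc_ctrl
    if len(d) < 2:
        raise ValueError("paired context test needs >= 2 guides")
    if np.allclose(d, d[0]):
        # zero-variance differences: the t statistic is undefined; report
        # p = 1 with a degenerate flag rather than a spurious certainty
        return 0.0, 1.0, True
    t, p = sps.ttest_rel(fc_fbx, fc_ctrl)
    return float(t), float(p), False


def gene_context_test(fc_table: pd.DataFrame,
                      alpha: float = DEFAULT_ALPHA,
                      adjust: bool = True) -> pd.DataFrame:
    """Per-gene two-tailed paired t test of guide FCs between contexts.

    ``fc_table`` has one row per guide with columns gene_id, fc_sgCTRL,
    fc_sgFBXO11.  q-values are BH across genes; a gene is classified when
    its q (or raw p when ``adjust`` is False) is below alpha, using the
    sign conventions of the context medians: the context with the larger
    absolute median fold change names the class, and the sign of that
    median decides enriched vs depleted.
    """
    rows: list[_GeneRow] = []
    for gene, sub in fc_table.groupby("gene_id", sort=True):
        fc_c = sub["fc_sgCTRL"].to_numpy(dtype=float)
        fc_f = sub["fc_sgFBXO11"].to_numpy(dtype=float)
        t, p, degen = _paired_test(fc_c, fc_f)
        rows.append(_GeneRow(
            gene_id=str(gene), n_guides=len(sub),
            median_fc_sgCTRL=float(np.median(fc_c)),
            median_fc_sgFBXO11=float(np.median(fc_f)),
            mean_paired_diff=float(np.mean(fc_f - fc_c)),
            t_statistic=t, p_value=p, degenerate=degen,
        ))
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    crit = out["q_value"] if adjust else out["p_value"]
    cls = []
    for i, row in out.iterrows():
        if row["degenerate"] or not (crit.iloc[i] < alpha):
            cls.append("none")
            continue
        if abs(row["median_fc_sgFBXO11"]) >= abs(row["median_fc_sgCTRL"]):
            ctx, med = "sgFBXO11", row["median_fc_sgFBXO11"]
        else:
            ctx, med = "sgCTRL", row["median_fc_sgCTRL"]
        if med == 0:
            cls.append("none")
        else:
            cls.append(f"{'enriched' if med > 0 else 'depleted'}_{ctx}")
    out["classification"] = cls
    return out


def analyze_screen(counts: pd.DataFrame,
                   n_replicates: int | None = None,
                   pseudocount: float = DEFAULT_PSEUDOCOUNT,
                   alpha: float = DEFAULT_ALPHA,
                   adjust: bool = True) -> pd.DataFrame:
    """Full screen analysis from a wide count table.

    ``counts`` carries guide_id, gene_id and sample columns named
    ``{context}_{timepoint}_rep{r}``.  Returns the per-gene context-test
    table.
    """
    sample_cols = [c for c in counts.columns if c not in ("guide_id", "gene_id")]
    if n_replicates is None:
        n_replicates = sum(c.startswith(screen_column(SCREEN_CONTEXTS[0],
                                                      SCREEN_TIMEPOINTS[0], 1)[:-1])
                           for c in sample_cols)
    cpm = cpm_normalize(counts[sample_cols])
    fc = {}
    for ctx in SCREEN_CONTEXTS:
        d10 = [screen_column(ctx, "day10", r) for r in range(1, n_replicates + 1)]
        d0 = [screen_column(ctx, "day0", r) for r in range(1, n_replicates + 1)]
        fc[f"fc_{ctx}"] = guide_log2fc(cpm, d10, d0, pseudocount)
    fc_table = pd.DataFrame({"gene_id": counts["gene_id"].to_numpy(), **fc},
                            index=counts.index)
    return gene_context_test(fc_table, alpha=alpha, adjust=adjust)
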