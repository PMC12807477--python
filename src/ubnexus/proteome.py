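"""Two-group LFQ proteome analysis.

Differential proteins (Welch t + BH), variable-protein PCA, correlation-
distance hierarchical clustering of samples, projection of protein fold
changes onto the interaction network, custom-gene-set permutation GSEA
(weighted Kolmogorov-Smirnov running sum), and proteome-transcriptome
fold-change correlation.  Quantities arrive as a protein x sample matrix
of positive LFQ intensities with absent values encoded as NaN; no
imputation is performed anywhere.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .stats import bh_adjust

DEFAULT_DE_P = 0.05
DEFAULT_DE_LFC = 0.5


def preprocess(matrix: pd.DataFrame,
               groups: pd.Series,
               min_presence_fraction: float = 0.5) -> pd.DataFrame:
    """log2-transform, presence-filter, and median-center the LFQ matrix.

    A protein is kept when it is quantified in at least
    ``min_presence_fraction`` of the samples of at least one group
    (dropped only when sparse in both).  Columns are median-centered in
    log2 space to remove per-sample loading offsets.
    """
    if not set(matrix.columns) <= set(groups.index):
        raise ValueError("group labels must cover all sample columns")
    if (matrix <= 0).any().any():
        raise ValueError("LFQ quantities must be positive or absent (NaN)")
    log2 = np.log2(matrix)
    keep = pd.Series(False, index=log2.index)
    for label in groups.unique():
        cols = groups.index[groups == label].intersection(log2.columns)
        frac = log2[cols].notna().mean(axis=1)
        keep |= frac >= min_presence_fraction
    log2 = log2.loc[keep]
    return log2 - log2.median(axis=0, skipna=True)


def differential_proteins(log2_matrix: pd.DataFrame,
                          groups: pd.Series,
                          case: str = "MDS",
                          control: str = "healthy",
                          p_cutoff: float = DEFAULT_DE_P,
                          lfc_cutoff: float = DEFAULT_DE_LFC) -> pd.DataFrame:
    """Per-protein Welch two-sided t test on available log2 values.

    log2FC is case minus control group mean.  Proteins with fewer than
    two quantified values in either group are skipped with a reason.
    ``significant`` means p < p_cutoff and |log2FC| > lfc_cutoff; BH
    q-values are reported alongside.
    """
    case_cols = groups.index[groups == case].intersection(log2_matrix.columns)
    ctrl_cols = groups.index[groups == control].intersection(log2_matrix.columns)
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    a = log2_matrix[case_cols].to_numpy(dtype=float)
    b = log2_matrix[ctrl_cols].to_numpy(dtype=float)
    n_a = np.isfinite(a).sum(axis=1)
    n_b = np.isfinite(b).sum(axis=1)
    testable = (n_a >= 2) & (n_b >= 2)

    lfc = np.nanmean(np.where(np.isfinite(a), a, np.nan), axis=1) - \
        np.nanmean(np.where(np.isfinite(b), b, np.nan), axis=1)
    t = np.full(len(log2_matrix), np.nan)
    p = np.full(len(log2_matrix), np.nan)
    if testable.any():
        res = sps.ttest_ind(a[testable], b[testable], axis=1,
                            equal_var=False, nan_policy="omit")
        t[testable] = res.statistic
        p[testable] = res.pvalue
    out = pd.DataFrame({
        "log2fc": lfc, "t_statistic": t, "p_value": p,
        "q_value": bh_adjust(p),
        "n_case": n_a, "n_control": n_b,
    }, index=log2_matrix.index)
    out["skipped_reason"] = np.where(testable, "", "insufficient_values")
    out["significant"] = (out["p_value"] < p_cutoff) & (out["log2fc"].abs() > lfc_cutoff)
    out["significant"] = out["significant"].fillna(False)
    return out


@dataclass
class PcaResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # proteins x components
    variance_explained: np.ndarray
    selected: pd.Index


def top_variable_pca(log2_matrix: pd.DataFrame,
                     fraction: float = 0.5,
                     scale: bool = False) -> PcaResult:
    """PCA of samples on the top-``fraction`` most variable proteins.

    Only fully quantified proteins enter (no imputation); rows are
    centered (and optionally unit-scaled) and the decomposition is a
    singular value decomposition of the sample x protein matrix.
    """
    complete = log2_matrix.dropna(axis=0)
    if complete.empty:
        raise ValueError("no fully quantified proteins available for PCA")
    variances = complete.var(axis=1, ddof=1)
    n_sel = max(1, int(round(fraction * len(complete))))
    selected = variances.sort_values(ascending=False).index[:n_sel]
    x = complete.loc[selected]
    x = x.sub(x.mean(axis=1), axis=0)
    if scale:
        sd = x.std(axis=1, ddof=1).replace(0, np.nan)
        x = x.div(sd, axis=0).dropna(axis=0)
    u, s, vt = np.linalg.svd(x.T.to_numpy(), full_matrices=False)
    k = len(s)
    comp = [f"PC{i+1}" for i in range(k)]
    scores = pd.DataFrame(u * s, index=x.columns, columns=comp)
    loadings = pd.DataFrame(vt.T, index=x.index, columns=comp)
    varexp = s ** 2 / np.sum(s ** 2)
    return PcaResult(scores=scores, loadings=loadings,
                     variance_explained=varexp, selected=selected)


@dataclass
class ClusterResult:
    sample_linkage: np.ndarray
    sample_order: list[str]
    sample_clusters: pd.Series
    row_clusters: pd.Series
    selected: pd.Index


def _correlation_distance(df: pd.DataFrame) -> np.ndarray:
    """1 - Pearson over columns of ``df`` (pairwise-complete), condensed."""
    corr = df.corr(min_periods=2).to_numpy()
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = np.nan_to_num(dist, nan=2.0)  # no overlap => maximally distant
    return squareform(dist, checks=False)


def hierarchical_cluster(log2_matrix: pd.DataFrame,
                         rank_p: pd.Series | None = None,
                         top_n: int = 400,
                         n_sample_clusters: int = 2,
                         n_row_clusters: int = 8) -> ClusterResult:
    """Average-linkage clustering with correlation distance.

    Rows are the ``top_n`` proteins ranked by differential significance
    (ascending p; all rows when ``rank_p`` is None), z-scored.  Sample
    and row dendrograms both use 1 - Pearson distance with average
    linkage; row clusters are cut at ``n_row_clusters`` to emulate
    numbered heatmap clusters.
    """
    if rank_p is not None:
        order = rank_p.reindex(log2_matrix.index).sort_values(kind="mergesort").index
        rows = order[:top_n]
    else:
        rows = log2_matrix.index[:top_n]
    x = log2_matrix.loc[rows]
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=0)
    x = x.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).dropna(axis=0, how="all")
    x = x[sd.reindex(x.index) > 0]

    z_samples = hierarchy.linkage(_correlation_distance(x), method="average")
    leaves = hierarchy.leaves_list(z_samples)
    sample_order = [x.columns[i] for i in leaves]
    sample_clusters = pd.Series(
        hierarchy.fcluster(z_samples, t=n_sample_clusters, criterion="maxclust"),
        index=x.columns, name="sample_cluster")

    z_rows = hierarchy.linkage(_correlation_distance(x.T), method="average")
    row_clusters = pd.Series(
        hierarchy.fcluster(z_rows, t=min(n_row_clusters, len(x)), criterion="maxclust"),
        index=x.index, name="row_cluster")
    return ClusterResult(sample_linkage=z_samples, sample_order=sample_order,
                         sample_clusters=sample_clusters,
                         row_clusters=row_clusters, selected=x.index)


def project_onto_network(de: pd.DataFrame,
                         network: nx.Graph) -> tuple[nx.Graph, dict]:
    """Attach per-protein log2FC to network nodes.

    Nodes absent from the DE table are flagged (``in_de`` False), never
    errored.  The summary reports the mean log2FC over mapped nodes.
    """
    g = network.copy()
    mapped = []
    for node in g.nodes:
        if node in de.index and np.isfinite(de.loc[node, "log2fc"]):
            g.nodes[node]["log2fc"] = float(de.loc[node, "log2fc"])
            g.nodes[node]["in_de"] = True
            mapped.append(float(de.loc[node, "log2fc"]))
        else:
            g.nodes[node]["in_de"] = False
    summary = {
        "n_nodes": g.number_of_nodes(),
        "n_mapped": len(mapped),
        "n_missing": g.number_of_nodes() - len(mapped),
        "mean_log2fc": float(np.mean(mapped)) if mapped else 0.0,
    }
    return g, summary


@dataclass
class EnrichmentResult:
    """Weighted-KS enrichment of one gene set in a ranked protein list."""

    set_name: str
    es: float
    nes: float
    p_value: float
    n_permutations: int
    seed: int | None
    n_ranked: int
    n_in_set: int


def _running_es(weights: np.ndarray, member: np.ndarray) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    n = len(member)
    n_hit = int(member.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must be a proper non-empty subset of the ranking")
    w_hit = weights * member
    denom = w_hit.sum()
    if denom == 0:
        hit = np.cumsum(member) / n_hit   # all-zero metric in set: unweighted
    else:
        hit = np.cumsum(w_hit) / denom
    miss = np.cumsum(~member) / (n - n_hit)
    dev = hit - miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


def _perm_es(weights: np.ndarray, n_hit: int, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """Null ES distribution by gene-label permutation of set membership."""
    n = len(weights)
    ranks = np.argsort(rng.random((n_perm, n)), axis=1)
    member = ranks < n_hit                             # n_hit random positions/row
    w_hit = weights[None, :] * member
    denom = w_hit.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    hit = np.cumsum(w_hit, axis=1) / denom
    miss = np.cumsum(~member, axis=1) / (n - n_hit)
    dev = hit - miss
    idx = np.argmax(np.abs(dev), axis=1)
    return dev[np.arange(n_perm), idx]


def gsea_custom_set(ranking: pd.Series,
                    gene_set: Iterable[str],
                    n_perm: int = 1000,
                    seed: int | None = None,
                    weight: float = 1.0,
                    set_name: str = "custom",
                    rng: np.random.Generator | None = None) -> EnrichmentResult:
    """Permutation GSEA of one custom set against a ranked metric.

    ``ranking`` maps protein id -> ranking metric (e.g. the Welch t
    statistic); it is sorted descending internally.  ES is the signed
    maximum of the |metric|^weight-weighted KS running sum; the null is
    gene-label permutation of set membership; NES divides ES by the mean
    |null ES| of matching sign; the p-value is the one-sided permutation
    tail with the +1 correction.
    """
    ranking = ranking.dropna().sort_values(ascending=False)
    member = ranking.index.isin(set(gene_set))
    weights = np.abs(ranking.to_numpy(dtype=float)) ** weight
    es = _running_es(weights, member)
    if rng is None:
        rng = np.random.default_rng(seed)
    null = _perm_es(weights, int(member.sum()), n_perm, rng)
    same_sign = null * np.sign(es) > 0
    if es == 0:
        nes, p = 0.0, 1.0
    elif same_sign.any():
        nes = es / np.mean(np.abs(null[same_sign]))
        # one-sided tail within the matching-sign null (standard GSEA
        # convention; keeps null p-values uniform)
        p = (1 + int(np.sum(same_sign & (np.abs(null) >= abs(es))))) \
            / (int(same_sign.sum()) + 1)
    else:  # no same-sign null: ES more extreme than every permutation
        nes = es / max(np.mean(np.abs(null)), np.finfo(float).tiny)
        p = 1.0 / (n_perm + 1)
    return EnrichmentResult(set_name=set_name, es=float(es), nes=float(nes),
                            p_value=float(p), n_permutations=n_perm, seed=seed,
                            n_ranked=len(ranking), n_in_set=int(member.sum()))


def fc_correlation(fc_a: pd.Series, fc_b: pd.Series) -> dict:
    """Pearson and Spearman correlation of fold changes on inner-joined ids."""
    joined = pd.concat([fc_a.rename("a"), fc_b.rename("b")], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("need >= 3 matched ids for a correlation")
    pr = sps.pearsonr(joined["a"], joined["b"])
    sr = sps.spearmanr(joined["a"], joined["b"])
    return {"pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
            "spearman_r": float(sr.statistic), "spearman_p": float(sr.pvalue),
            "n_matched": n}
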