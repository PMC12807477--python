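"""LFQ preprocessing, DE, PCA, clustering, network projection, GSEA."""
import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats as sps

from oracles import (bh_step_up, gsea_running_sum_loop, upgma_merge_heights,
                     welch_t_formula)
from ubnexus.proteome import (differential_proteins, fc_correlation,
                              gsea_custom_set, hierarchical_cluster,
                              preprocess, project_onto_network,
                              top_variable_pca)
from ubnexus.stats import bh_adjust


def _matrix(rng, n_prot=40, n_a=5, n_b=5, missing=0.0, noise_sd=1.0):
    cols = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    m = pd.DataFrame(2.0 ** rng.normal(20, noise_sd, size=(n_prot, len(cols))),
                     index=[f"P{i}" for i in range(n_prot)], columns=cols)
    if missing:
        m = m.mask(rng.random(m.shape) < missing)
    groups = pd.Series(["MDS"] * n_a + ["healthy"] * n_b, index=cols)
    return m, groups


def test_preprocess_shape_filter_and_centering(rng):
    m, groups = _matrix(rng)
    out = preprocess(m, groups)
    assert out.shape == m.shape                       # fully present: kept
    assert np.allclose(out.median(axis=0), 0.0)       # column medians centered
    m2 = m.copy()
    m2.iloc[0, :] = np.nan                            # absent everywhere
    out2 = preprocess(m2, groups)
    assert m2.index[0] not in out2.index


def test_bh_matches_step_up_oracle(rng):
    for _ in range(20):
        p = rng.uniform(0, 1, size=int(rng.integers(3, 40)))
        assert np.allclose(bh_adjust(p), bh_step_up(p), rtol=1e-12)


def test_welch_matches_formula_oracle(rng):
    m, groups = _matrix(rng, n_prot=10, n_a=3, n_b=3)
    log2m = preprocess(m, groups)
    de = differential_proteins(log2m, groups)
    for pid in log2m.index:
        a = log2m.loc[pid, groups.index[groups == "MDS"]].to_numpy()
        b = log2m.loc[pid, groups.index[groups == "healthy"]].to_numpy()
        t_ref, p_ref = welch_t_formula(a, b)
        assert de.loc[pid, "t_statistic"] == pytest.approx(t_ref, rel=1e-9)
        assert de.loc[pid, "p_value"] == pytest.approx(p_ref, rel=1e-9)
        assert de.loc[pid, "log2fc"] == pytest.approx(a.mean() - b.mean(), rel=1e-9)


def test_identical_groups_give_null_results(rng):
    m, groups = _matrix(rng, n_a=4, n_b=4)
    half = m[groups.index[groups == "MDS"]]
    dup = pd.concat([half, half.rename(columns=dict(
        zip(half.columns, groups.index[groups == "healthy"])))], axis=1)
    de = differential_proteins(preprocess(dup, groups), groups)
    assert np.allclose(de["log2fc"], 0.0, atol=1e-10)
    assert (de["p_value"] > 0.99).all()


def test_planted_shift_recovered(rng):
    m, groups = _matrix(rng, n_prot=100, n_a=6, n_b=6, noise_sd=0.4)
    shifted = m.index[:10]
    m.loc[shifted, groups.index[groups == "MDS"]] *= 2 ** 1.5
    de = differential_proteins(preprocess(m, groups), groups)
    assert de.loc[shifted, "significant"].mean() >= 0.9


def test_insufficient_values_skipped(rng):
    m, groups = _matrix(rng, n_prot=5, n_a=3, n_b=3)
    m.iloc[0, [0, 1]] = np.nan  # one MDS value left
    log2m = np.log2(m)
    de = differential_proteins(log2m, groups)
    assert de.iloc[0]["skipped_reason"] == "insufficient_values"
    assert not de.iloc[0]["significant"]


def test_pca_selection_and_variance(rng):
    m, groups = _matrix(rng, n_prot=10)
    res = top_variable_pca(preprocess(m, groups), fraction=0.5)
    assert len(res.selected) == 5
    assert res.variance_explained.sum() <= 1.0 + 1e-9
    assert np.all(np.diff(res.variance_explained) <= 1e-9)


def test_pca_separates_planted_clusters(rng):
    m, groups = _matrix(rng, n_prot=60, n_a=6, n_b=6)
    m.loc[m.index[:30], groups.index[groups == "MDS"]] *= 2 ** 2.0
    res = top_variable_pca(preprocess(m, groups), fraction=0.5)
    pc1 = res.scores["PC1"]
    a = pc1[groups.index[groups == "MDS"]]
    b = pc1[groups.index[groups == "healthy"]]
    assert (a.max() < b.min()) or (b.max() < a.min())


def test_duplicate_samples_merge_at_zero(rng):
    m, groups = _matrix(rng, n_prot=30, n_a=3, n_b=3)
    m["B0"] = m["A0"]  # duplicate column
    res = hierarchical_cluster(np.log2(m), top_n=30)
    # the first merge joins the duplicated pair at height ~0
    assert res.sample_linkage[0, 2] == pytest.approx(0.0, abs=1e-10)


def test_average_linkage_matches_bruteforce_agglomeration(rng):
    for _ in range(20):
        n = int(rng.integers(4, 8))
        d = rng.uniform(0.1, 2.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        z = hierarchy.linkage(squareform(d, checks=False), method="average")
        assert np.allclose(sorted(z[:, 2]), upgma_merge_heights(d), rtol=1e-9)


def test_two_block_matrix_separates_sample_clusters(rng):
    m, groups = _matrix(rng, n_prot=80, n_a=6, n_b=6)
    m.loc[m.index[:40], groups.index[groups == "MDS"]] *= 2 ** 2.0
    res = hierarchical_cluster(preprocess(m, groups), top_n=80,
                               n_sample_clusters=2)
    labels = res.sample_clusters
    mds = labels[groups.index[groups == "MDS"]]
    hc = labels[groups.index[groups == "healthy"]]
    assert mds.nunique() == 1 and hc.nunique() == 1 and mds.iloc[0] != hc.iloc[0]


def test_network_projection_flags_missing_nodes():
    de = pd.DataFrame({"log2fc": [0.0, -1.0]}, index=["A", "B"])
    g = nx.Graph()
    g.add_edge("A", "B", confidence=0.9)
    g.add_node("Z")
    net, summary = project_onto_network(de, g)
    assert net.nodes["A"]["in_de"] and not net.nodes["Z"]["in_de"]
    assert summary["n_missing"] == 1
    assert summary["mean_log2fc"] == pytest.approx(-0.5)
    all_zero = pd.DataFrame({"log2fc": [0.0, 0.0]}, index=["A", "B"])
    assert project_onto_network(all_zero, g)[1]["mean_log2fc"] == 0.0


def test_gsea_top_k_set_is_extremal(rng):
    ranking = pd.Series(np.sort(rng.normal(0, 1, 50))[::-1],
                        index=[f"P{i}" for i in range(50)])
    top = gsea_custom_set(ranking, [f"P{i}" for i in range(5)],
                          n_perm=100, seed=1)
    assert top.es > 0
    for _ in range(10):  # no same-size set scores higher
        members = rng.choice(50, size=5, replace=False)
        other = gsea_custom_set(ranking, [f"P{i}" for i in members],
                                n_perm=10, seed=1)
        assert other.es <= top.es + 1e-12


def test_gsea_running_sum_matches_hand_enumeration():
    ranking = pd.Series([3.0, 2.0, 1.0, 0.5], index=list("abcd"))
    res = gsea_custom_set(ranking, ["b"], n_perm=10, seed=0, weight=1.0)
    # hand computation: hit at position 2 contributes 1; misses 1/3 each
    # running sum: [-1/3, 1 - 1/3, 1 - 2/3, 1 - 1] -> max deviation 2/3
    assert res.es == pytest.approx(2.0 / 3.0, rel=1e-12)


def test_gsea_matches_loop_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(10, 40))
        metric = np.sort(rng.normal(0, 2, n))[::-1]
        ranking = pd.Series(metric, index=[f"P{i}" for i in range(n)])
        k = int(rng.integers(1, n // 2))
        members = set(rng.choice(n, size=k, replace=False))
        gene_set = [f"P{i}" for i in members]
        res = gsea_custom_set(ranking, gene_set, n_perm=10, seed=0)
        mask = np.array([i in members for i in range(n)])
        assert res.es == pytest.approx(
            gsea_running_sum_loop(metric, mask), rel=1e-9)


def test_gsea_unweighted_es_invariant_to_monotone_transform(rng):
    n = 30
    metric = np.sort(rng.normal(0, 1, n))[::-1]
    ranking = pd.Series(metric, index=[f"P{i}" for i in range(n)])
    gene_set = [f"P{i}" for i in range(0, n, 4)]
    a = gsea_custom_set(ranking, gene_set, n_perm=10, seed=0, weight=0.0)
    transformed = pd.Series(np.exp(metric) + 5.0, index=ranking.index)
    b = gsea_custom_set(transformed, gene_set, n_perm=10, seed=0, weight=0.0)
    assert a.es == pytest.approx(b.es, rel=1e-12)


def test_gsea_null_calibration(rng):
    n = 200
    ranking = pd.Series(rng.normal(0, 1, n), index=[f"P{i}" for i in range(n)])
    nes_vals, p_vals = [], []
    for s in range(60):
        members = rng.choice(n, size=15, replace=False)
        res = gsea_custom_set(ranking, [f"P{i}" for i in members],
                              n_perm=200, seed=s)
        nes_vals.append(res.nes)
        p_vals.append(res.p_value)
    assert 0.6 < np.mean(np.abs(nes_vals)) < 1.5   # |NES| normalized near 1
    assert sps.kstest(p_vals, "uniform").pvalue > 0.001


def test_fc_correlation_identity_and_matching():
    a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    res = fc_correlation(a, a)
    assert res["pearson_r"] == pytest.approx(1.0)
    assert res["spearman_r"] == pytest.approx(1.0)
    b = pd.Series([0.5, 0.1, 0.9, 0.2], index=list("bcdx"))
    assert fc_correlation(a, b)["n_matched"] == 3  # intersection size
    with pytest.raises(ValueError):
        fc_correlation(a, pd.Series([1.0], index=["a"]))


def test_fc_correlation_independent_vectors_near_zero(rng):
    ids = [f"P{i}" for i in range(2000)]
    a = pd.Series(rng.normal(0, 1, 2000), index=ids)
    b = pd.Series(rng.normal(0, 1, 2000), index=ids)
    res = fc_correlation(a, b)
    assert abs(res["pearson_r"]) < 3 / np.sqrt(2000)
    assert res["n_matched"] == 2000
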