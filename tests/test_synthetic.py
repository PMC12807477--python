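"""Generator contracts: determinism, truth consistency, planted effects."""
import numpy as np
import pandas as pd
import pytest

from ubnexus.config import ConfigurationError, ImageSimConfig, SimConfig
from ubnexus.synthetic import (ellipse_mask, gen_guide_counts,
                               gen_nucleus_images, gen_spectral_counts,
                               gen_ub_peptides, simulate_all, stream_rngs,
                               ub_condition_columns)
from ubnexus.ubiquitylome import site_log2fc


def test_same_seed_gives_bit_identical_outputs(small_sim):
    b1 = simulate_all(small_sim)
    b2 = simulate_all(small_sim)
    pd.testing.assert_frame_equal(b1.ub_table, b2.ub_table)
    pd.testing.assert_frame_equal(b1.guide_counts, b2.guide_counts)
    pd.testing.assert_frame_equal(b1.lfq_matrix, b2.lfq_matrix)
    pd.testing.assert_frame_equal(b1.splice.inclusion, b2.splice.inclusion)
    for a, b in zip(b1.images_control, b2.images_control):
        assert np.array_equal(a, b)
    assert b1.truth.to_dict() == b2.truth.to_dict()


def test_different_seeds_differ(small_sim):
    other = SimConfig(**{**small_sim.__dict__, "seed": small_sim.seed + 1})
    b1 = simulate_all(small_sim)
    b2 = simulate_all(other)
    assert not b1.ub_table.equals(b2.ub_table)


def test_truth_ids_are_subset_of_emitted_tables(small_sim):
    b = simulate_all(small_sim)
    assert b.truth.lost_ub_proteins <= set(b.ub_table["protein_id"])
    assert b.truth.interactors <= set(b.spectral_counts["protein_id"])
    assert set(b.truth.context_genes) <= set(b.guide_counts["gene_id"])
    assert set(b.truth.de_proteins) <= set(b.lfq_matrix.index)
    assert set(b.truth.splice_events) <= set(b.splice.meta.index)
    assert all(np.isfinite(v) for v in b.truth.context_genes.values())
    assert all(np.isfinite(v) for v in b.truth.de_proteins.values())


def test_full_evidence_is_triple_intersection(small_sim):
    t = simulate_all(small_sim).truth
    triple = t.lost_ub_proteins & t.interactors & set(t.context_genes)
    assert triple == t.full_evidence
    assert len(t.full_evidence) == small_sim.n_full_evidence


def test_zero_noise_ub_log2fc_is_exact():
    cfg = SimConfig(seed=3, n_proteins=20, n_lost_ub=4, n_interactors=3,
                    n_context_genes=3)
    cfg.ub.noise_sd = 0.0
    cfg.ub.effect = 1.0
    table, planted = gen_ub_peptides(cfg)
    ko, wt = ub_condition_columns(cfg.ub.n_replicates)
    res = site_log2fc(table, ko, wt, pseudocount=0.0)
    planted_rows = res["protein_id"].isin(planted)
    assert np.allclose(res.loc[planted_rows, "log2fc"], -1.0)
    assert np.allclose(res.loc[~planted_rows, "log2fc"], 0.0)


def test_null_site_log2fc_mean_near_zero():
    cfg = SimConfig(seed=11, n_proteins=400, n_lost_ub=2, n_interactors=2,
                    n_context_genes=2, n_full_evidence=2)
    table, planted = gen_ub_peptides(cfg)
    ko, wt = ub_condition_columns(cfg.ub.n_replicates)
    res = site_log2fc(table, ko, wt)
    null = res[~res["protein_id"].isin(planted)]["log2fc"]
    se = null.std(ddof=1) / np.sqrt(len(null))
    assert abs(null.mean()) < 3 * se + 1e-12
    assert len(null) >= 400


def test_spectral_count_totals_conserved(small_sim):
    table, _ = gen_spectral_counts(small_sim)
    assert table["count_ip"].sum() == small_sim.ip.total_ip
    assert table["count_igg"].sum() == small_sim.ip.total_igg


def test_spectral_fold_below_one_rejected(small_sim):
    small_sim.ip.fold = 0.5
    with pytest.raises(ConfigurationError):
        small_sim.ip.validate()


def test_guide_counts_zero_effect_zero_dispersion_flat():
    cfg = SimConfig(seed=5, n_proteins=10, n_lost_ub=2, n_interactors=2,
                    n_context_genes=2)
    cfg.screen.dispersion = 0.0
    cfg.screen.effect = 0.0
    counts, _ = gen_guide_counts(cfg)
    cols = [c for c in counts.columns if c not in ("guide_id", "gene_id")]
    day0 = counts[[c for c in cols if "day0" in c]].to_numpy()
    day10 = counts[[c for c in cols if "day10" in c]].to_numpy()
    assert np.array_equal(day0, day10)


def test_guide_counts_planted_effect_exact_at_zero_dispersion():
    cfg = SimConfig(seed=5, n_proteins=10, n_lost_ub=2, n_interactors=2,
                    n_context_genes=2)
    cfg.screen.dispersion = 0.0
    counts, effects = gen_guide_counts(cfg)
    gene, eff = next(iter(effects.items()))
    sub = counts[counts["gene_id"] == gene]
    d0 = sub["sgFBXO11_day0_rep1"].to_numpy(dtype=float)
    d10 = sub["sgFBXO11_day10_rep1"].to_numpy(dtype=float)
    # means are rounded to integers, so the recovered log2FC is exact to
    # within rounding of counts in the hundreds
    assert np.allclose(np.log2(d10 / d0), eff, atol=0.02)
    c0 = sub["sgCTRL_day0_rep1"].to_numpy(dtype=float)
    c10 = sub["sgCTRL_day10_rep1"].to_numpy(dtype=float)
    assert np.array_equal(c0, c10)


def test_lfq_network_shift_and_missingness(small_sim):
    b = simulate_all(small_sim)
    observed = b.lfq_matrix.isna().to_numpy().mean()
    rate = small_sim.lfq.missing_rate
    n = b.lfq_matrix.size
    assert abs(observed - rate) < 4 * np.sqrt(rate * (1 - rate) / n)
    # planted network nodes are shifted down in the disease group
    log2 = np.log2(b.lfq_matrix)
    dis = b.lfq_groups.index[b.lfq_groups == "MDS"]
    hc = b.lfq_groups.index[b.lfq_groups == "healthy"]
    nodes = sorted(b.truth.interactors)
    diff = (log2.loc[nodes, dis].mean(axis=1)
            - log2.loc[nodes, hc].mean(axis=1))
    assert diff.mean() < -0.5


def test_splice_counts_match_planted_psi_at_depth():
    cfg = SimConfig(seed=9)
    cfg.splice.depth = 5000.0
    cfg.splice.n_events = 50
    cfg.splice.n_planted = 0
    cfg.splice.psi_min = cfg.splice.psi_max = 0.5
    from ubnexus.synthetic import gen_splicing_counts
    table, _ = gen_splicing_counts(cfg)
    psi = table.inclusion.to_numpy() / (table.inclusion + table.skipping).to_numpy()
    assert abs(psi.mean() - 0.5) < 0.01


def test_images_zero_noise_object_count_and_geometry(rng):
    icfg = ImageSimConfig(n_images=1, noise_sd=0.0, n_objects=3)
    stacks, objects = gen_nucleus_images(icfg, rng)
    from skimage import measure
    npm1 = stacks[0][1]
    bright = npm1 >= icfg.npm1_bright_level
    labels = measure.label(bright, connectivity=2)
    assert labels.max() == 3
    assert len(objects[0]) == 3
    # all objects inside the nucleus mask
    nuc = stacks[0][0] > icfg.dapi_level / 2
    assert bright[~nuc].sum() == 0


def test_ellipse_mask_area_close_to_analytic():
    m = ellipse_mask((128, 128), (64, 64), (30, 20))
    assert abs(m.sum() - np.pi * 30 * 20) / (np.pi * 30 * 20) < 0.02


def test_stream_rng_expansion_is_stable():
    r1 = stream_rngs(42)
    r2 = stream_rngs(42)
    assert r1["ub"].integers(1 << 30) == r2["ub"].integers(1 << 30)
    # consuming one stream leaves the others untouched
    r3 = stream_rngs(42)
    r3["ip"].integers(1 << 30, size=100)
    r4 = stream_rngs(42)
    assert r3["splice"].integers(1 << 30) == r4["splice"].integers(1 << 30)
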