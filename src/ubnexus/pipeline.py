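"""End-to-end orchestration: one config in, a machine-readable report out.

Runs synthetic generation (or loads inputs from disk), then every
analysis stage in dependency order, writing intermediates under the
configured output directory and a deterministic JSON run report with
per-file checksums.  Any stage failure halts the run with a
stage-tagged error.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import imaging, integration, ip_enrichment, proteome, screen, splicing
from . import ubiquitylome
from .config import RunConfig, config_to_dict
from .io import (read_image_stack, read_tsv, sha256_file, write_gmt,
                 write_image_stack, write_tsv)
from .splicing import SpliceEventTable
from .synthetic import SimBundle, SimTruth, simulate_all, ub_condition_columns


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunReport:
    """Counts, parameters and checksums of one pipeline run."""

    parameters: dict[str, Any]
    counts: dict[str, int]
    nominations: list[str]
    gsea: dict[str, float]
    imaging_summary: dict[str, dict[str, float]]
    fc_correlation: dict[str, float]
    checksums: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _load_inputs(cfg: RunConfig) -> SimBundle:
    req = ["ub_table", "spectral_counts", "guide_counts", "lfq_matrix",
           "lfq_groups", "transcriptome_fc", "splice_meta", "splice_inclusion",
           "splice_skipping", "expression", "network_edges",
           "images_control", "images_fbxo11_low", "truth"]
    missing = [k for k in req if k not in cfg.inputs
               or not Path(cfg.inputs[k]).exists()]
    if missing:
        raise StageError("inputs", f"missing input paths (and simulate=False): {missing}")
    groups = read_tsv(cfg.inputs["lfq_groups"], index_col=0)["group"]
    splice = SpliceEventTable(
        meta=read_tsv(cfg.inputs["splice_meta"], index_col=0),
        inclusion=read_tsv(cfg.inputs["splice_inclusion"], index_col=0),
        skipping=read_tsv(cfg.inputs["splice_skipping"], index_col=0),
    )
    images_c = [read_image_stack(p)[0]
                for p in sorted(Path(cfg.inputs["images_control"]).glob("*.tif*"))]
    images_l = [read_image_stack(p)[0]
                for p in sorted(Path(cfg.inputs["images_fbxo11_low"]).glob("*.tif*"))]
    return SimBundle(
        ub_table=read_tsv(cfg.inputs["ub_table"]),
        spectral_counts=read_tsv(cfg.inputs["spectral_counts"]),
        guide_counts=read_tsv(cfg.inputs["guide_counts"]),
        lfq_matrix=read_tsv(cfg.inputs["lfq_matrix"], index_col=0),
        lfq_groups=groups,
        transcriptome_fc=read_tsv(cfg.inputs["transcriptome_fc"],
                                  index_col=0).iloc[:, 0],
        splice=splice,
        expression=read_tsv(cfg.inputs["expression"], index_col=0).iloc[:, 0],
        network_edges=read_tsv(cfg.inputs["network_edges"]),
        images_control=images_c,
        images_fbxo11_low=images_l,
        truth=SimTruth.from_json(cfg.inputs["truth"]),
    )


def write_inputs(bundle: SimBundle, outdir: Path, cfg: RunConfig) -> None:
    d = outdir / "inputs"
    d.mkdir(parents=True, exist_ok=True)
    write_tsv(bundle.ub_table, d / "ub_peptides.tsv")
    write_tsv(bundle.spectral_counts, d / "spectral_counts.tsv")
    write_tsv(bundle.guide_counts, d / "guide_counts.tsv")
    write_tsv(bundle.lfq_matrix, d / "lfq_matrix.tsv", index=True)
    write_tsv(bundle.lfq_groups.to_frame(), d / "lfq_groups.tsv", index=True)
    write_tsv(bundle.transcriptome_fc.to_frame(), d / "transcriptome_fc.tsv", index=True)
    write_tsv(bundle.splice.meta, d / "splice_meta.tsv", index=True)
    write_tsv(bundle.splice.inclusion, d / "splice_inclusion.tsv", index=True)
    write_tsv(bundle.splice.skipping, d / "splice_skipping.tsv", index=True)
    write_tsv(bundle.expression.to_frame(), d / "expression.tsv", index=True)
    write_tsv(bundle.network_edges, d / "network_edges.tsv")
    write_gmt({"interactome": sorted(bundle.truth.interactors)},
              d / "gene_sets.gmt")
    bundle.truth.to_json(d / "truth.json")
    for cond, stacks in (("control", bundle.images_control),
                         ("fbxo11_low", bundle.images_fbxo11_low)):
        (d / f"images_{cond}").mkdir(exist_ok=True)
        for i, st in enumerate(stacks):
            write_image_stack(d / f"images_{cond}" / f"nucleus_{i:02d}.tif", st)


def quantify_images(stacks: list[np.ndarray]) -> pd.DataFrame:
    rows = []
    for i, stack in enumerate(stacks):
        dapi, npm1, fb = stack[0], stack[1], stack[2]
        for roi in imaging.segment_nuclei(dapi):
            comp = imaging.bright_mask(npm1, roi)
            shapes = imaging.object_shapes(comp.bright, min_area=20)
            mfi_n, sd_n = imaging.nucleus_intensity_stats(npm1, roi)
            mfi_f, sd_f = imaging.nucleus_intensity_stats(fb, roi)
            try:
                r_bright, r_dim = imaging.compartment_pearson(
                    npm1, fb, comp.bright, comp.dim)
            except ValueError:
                r_bright, r_dim = float("nan"), float("nan")
            rows.append({
                "image": i, "nucleus": roi.label,
                "n_objects": len(shapes),
                "median_circularity": float(np.median([s.circularity for s in shapes]))
                if shapes else float("nan"),
                "median_aspect_ratio": float(np.median([s.aspect_ratio for s in shapes]))
                if shapes else float("nan"),
                "median_object_area": float(np.median([s.area for s in shapes]))
                if shapes else float("nan"),
                "pearson_bright": r_bright, "pearson_dim": r_dim,
                "mfi_npm1": mfi_n, "sd_npm1": sd_n,
                "mfi_fbxo11": mfi_f, "sd_fbxo11": sd_f,
            })
    return pd.DataFrame(rows)


def run_all(cfg: RunConfig) -> RunReport:
    """Execute every stage; returns (and writes) the run report."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = cfg.thresholds

    # -- inputs -------------------------------------------------------------
    try:
        bundle = simulate_all(cfg.sim) if cfg.simulate else _load_inputs(cfg)
        write_inputs(bundle, outdir, cfg)
    except StageError:
        raise
    except Exception as e:
        raise StageError("inputs", str(e)) from e

    counts: dict[str, int] = {}

    # -- ubiquitylome -------------------------------------------------------
    try:
        ko_cols, wt_cols = ub_condition_columns(cfg.sim.ub.n_replicates)
        sites = ubiquitylome.site_log2fc(bundle.ub_table, ko_cols, wt_cols,
                                         threshold=th.ub_log2fc)
        lost = ubiquitylome.flag_lost_ub(sites, threshold=th.ub_log2fc)
        write_tsv(sites, outdir / "ub_sites.tsv")
        write_tsv(lost, outdir / "ub_lost_proteins.tsv")
        counts["sites_flagged"] = int(sites["passes_filter"].sum())
        counts["proteins_lost_ub"] = int(lost["lost_ub"].sum())
    except Exception as e:
        raise StageError("ubiquitylome", str(e)) from e

    # -- IP enrichment + network -------------------------------------------
    try:
        calls = ip_enrichment.call_interactors(bundle.spectral_counts,
                                               alpha=th.ip_alpha,
                                               fold_cutoff=th.ip_fold)
        whitelist = set(calls.loc[calls["in_box"], "protein_id"]) | {cfg.sim.bait_id}
        network = ip_enrichment.assemble_network(
            bundle.network_edges, confidence_cutoff=th.network_confidence,
            node_whitelist=whitelist)
        write_tsv(calls, outdir / "interactor_calls.tsv")
        edges = pd.DataFrame(
            [(a, b, d["confidence"]) for a, b, d in network.edges(data=True)],
            columns=["node_a", "node_b", "confidence"])
        write_tsv(edges, outdir / "network_edges_filtered.tsv")
        counts["interactors_called"] = int(calls["in_box"].sum())
        counts["network_nodes"] = network.number_of_nodes()
        counts["network_edges"] = network.number_of_edges()
    except Exception as e:
        raise StageError("ip_enrichment", str(e)) from e

    # -- screen -------------------------------------------------------------
    try:
        screen_res = screen.analyze_screen(bundle.guide_counts,
                                           n_replicates=cfg.sim.screen.n_replicates,
                                           alpha=th.screen_alpha)
        write_tsv(screen_res, outdir / "screen_results.tsv")
        counts["genes_classified"] = int((screen_res["classification"] != "none").sum())
    except Exception as e:
        raise StageError("screen", str(e)) from e

    # -- integration ---------------------------------------------------------
    try:
        profiles = integration.build_profiles(lost, calls, screen_res)
        noms = integration.nominate(profiles)
        write_tsv(noms, outdir / "nominations.tsv")
        nominated = noms.loc[noms["nominated"], "protein_id"].tolist()
        counts["nominated"] = len(nominated)
    except Exception as e:
        raise StageError("integration", str(e)) from e

    # -- proteome ------------------------------------------------------------
    try:
        log2m = proteome.preprocess(bundle.lfq_matrix, bundle.lfq_groups)
        de = proteome.differential_proteins(log2m, bundle.lfq_groups,
                                            p_cutoff=th.de_p,
                                            lfc_cutoff=th.de_log2fc)
        write_tsv(de, outdir / "proteome_de.tsv", index=True)
        counts["proteins_tested"] = int((de["skipped_reason"] == "").sum())
        counts["proteins_significant"] = int(de["significant"].sum())

        pca = proteome.top_variable_pca(log2m, fraction=0.5)
        write_tsv(pca.scores, outdir / "pca_scores.tsv", index=True)

        clus = proteome.hierarchical_cluster(log2m, rank_p=de["p_value"], top_n=400)
        write_tsv(clus.sample_clusters.to_frame(), outdir / "sample_clusters.tsv",
                  index=True)
        write_tsv(clus.row_clusters.to_frame(), outdir / "row_clusters.tsv",
                  index=True)

        proj_net, proj_summary = proteome.project_onto_network(de, network)
        node_attrs = pd.DataFrame(
            [(n, d.get("log2fc", np.nan), d["in_de"])
             for n, d in proj_net.nodes(data=True)],
            columns=["protein_id", "log2fc", "in_de"])
        write_tsv(node_attrs, outdir / "network_node_attributes.tsv")
        counts["network_nodes_mapped"] = int(proj_summary["n_mapped"])

        interactome = sorted(set(bundle.truth.interactors) & set(de.index))
        enr = proteome.gsea_custom_set(de["t_statistic"], interactome,
                                       n_perm=cfg.n_perm, seed=cfg.sim.seed,
                                       set_name="interactome")
        gsea = {"es": enr.es, "nes": enr.nes, "p_value": enr.p_value,
                "n_permutations": enr.n_permutations, "n_in_set": enr.n_in_set,
                "mean_network_log2fc": proj_summary["mean_log2fc"]}

        fc_corr = proteome.fc_correlation(de["log2fc"], bundle.transcriptome_fc)
    except Exception as e:
        raise StageError("proteome", str(e)) from e

    # -- splicing ------------------------------------------------------------
    try:
        from .synthetic import splice_sample_columns
        g1, g2 = splice_sample_columns(cfg.sim.splice.n_group1,
                                       cfg.sim.splice.n_group2)
        psi_res = splicing.event_test(bundle.splice, g1, g2,
                                      fdr_cutoff=th.splice_fdr,
                                      p_cutoff=th.splice_p,
                                      dpsi_cutoff=th.splice_dpsi)
        write_tsv(psi_res, outdir / "splice_results.tsv", index=True)
        passing, type_counts = splicing.filter_events(psi_res)
        counts["splice_events_passing"] = len(passing)
        quart = splicing.quartile_groups(bundle.expression)
        counts["samples_expression_high"] = len(quart.high)
        counts["samples_expression_low"] = len(quart.low)
    except Exception as e:
        raise StageError("splicing", str(e)) from e

    # -- imaging -------------------------------------------------------------
    try:
        img_summaries = {}
        for cond, stacks in (("control", bundle.images_control),
                             ("fbxo11_low", bundle.images_fbxo11_low)):
            q = quantify_images(stacks)
            write_tsv(q, outdir / f"imaging_{cond}.tsv")
            img_summaries[cond] = {
                "n_nuclei": int(len(q)),
                "median_objects": float(q["n_objects"].median()),
                "median_circularity": float(q["median_circularity"].median()),
                "median_aspect_ratio": float(q["median_aspect_ratio"].median()),
                "median_object_area": float(q["median_object_area"].median()),
                "median_pearson_dim": float(q["pearson_dim"].median()),
                "median_pearson_bright": float(q["pearson_bright"].median()),
            }
            counts[f"nuclei_quantified_{cond}"] = int(len(q))
    except Exception as e:
        raise StageError("imaging", str(e)) from e

    # -- report --------------------------------------------------------------
    files = sorted(p for p in outdir.rglob("*")
                   if p.is_file() and p.name not in ("report.json", "report.txt"))
    checksums = {str(p.relative_to(outdir)): sha256_file(p) for p in files}
    report = RunReport(
        parameters=config_to_dict(cfg),
        counts=counts,
        nominations=nominated,
        gsea=gsea,
        imaging_summary=img_summaries,
        fc_correlation=fc_corr,
        checksums=checksums,
    )
    report.write(outdir / "report.json")
    lines = ["pipeline run report", "===================", ""]
    for k, v in sorted(counts.items()):
        lines.append(f"{k}: {v}")
    lines.append(f"nominated substrates: {', '.join(nominated) or '(none)'}")
    lines.append(f"interactome GSEA: ES={gsea['es']:.3f} NES={gsea['nes']:.3f} "
                 f"p={gsea['p_value']:.4g}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return report
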