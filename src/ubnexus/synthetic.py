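"""Seeded synthetic benchmark: every input stream with planted ground truth.

The generators emulate the six data streams the pipeline consumes —
KO-vs-WT diGly peptide intensities, IP-vs-IgG spectral counts,
day0/day10 guide counts in two CRISPR contexts, a two-group LFQ proteome
matrix, inclusion/skipping junction counts, and multi-channel nucleus
images — each with a machine-readable record of what was planted.

Determinism contract: a single global seed is expanded into per-stream
substreams via ``numpy.random.SeedSequence.spawn`` in the fixed order
``design, ub, ip, screen, lfq, splice, image_control, image_fbxo11_low,
network``.  Adding a stream appends to that order, so existing streams
are never perturbed.  Same config + same seed => bit-identical outputs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .config import (ConfigurationError, ImageSimConfig, SimConfig)

# Substream expansion order. Append only; never reorder.
STREAMS = ("design", "ub", "ip", "screen", "lfq", "splice",
           "image_control", "image_fbxo11_low", "network")

CHANNELS = ("DAPI", "NPM1", "FBXO11")

SCREEN_CONTEXTS = ("sgCTRL", "sgFBXO11")
SCREEN_TIMEPOINTS = ("day0", "day10")


def stream_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Expand one global seed into the documented per-stream generators."""
    children = np.random.SeedSequence(seed).spawn(len(STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(STREAMS, children)}


def protein_universe(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# Ground truth record

@dataclass
class SimTruth:
    """What was planted, per stream.  Ids always exist in the emitted tables."""

    lost_ub_proteins: set[str] = field(default_factory=set)
    interactors: set[str] = field(default_factory=set)
    context_genes: dict[str, float] = field(default_factory=dict)   # signed log2 effect
    de_proteins: dict[str, float] = field(default_factory=dict)     # true log2FC
    splice_events: dict[str, float] = field(default_factory=dict)   # true delta-PSI
    objects_per_image: dict[str, list[list[dict[str, Any]]]] = field(default_factory=dict)
    full_evidence: set[str] = field(default_factory=set)

    def to_dict(self) -> dict[str, Any]:
        return {
            "lost_ub_proteins": sorted(self.lost_ub_proteins),
            "interactors": sorted(self.interactors),
            "context_genes": dict(sorted(self.context_genes.items())),
            "de_proteins": dict(sorted(self.de_proteins.items())),
            "splice_events": dict(sorted(self.splice_events.items())),
            "objects_per_image": self.objects_per_image,
            "full_evidence": sorted(self.full_evidence),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @staticmethod
    def from_json(path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return SimTruth(
            lost_ub_proteins=set(d["lost_ub_proteins"]),
            interactors=set(d["interactors"]),
            context_genes=d["context_genes"],
            de_proteins=d["de_proteins"],
            splice_events=d["splice_events"],
            objects_per_image=d["objects_per_image"],
            full_evidence=set(d["full_evidence"]),
        )


def plant_design(cfg: SimConfig, rng: np.random.Generator
                 ) -> tuple[set[str], set[str], dict[str, float], set[str]]:
    """Choose the planted sets over the shared protein universe.

    The two (by default) full-evidence proteins appear in all three
    streams; the remaining planted ids are drawn from disjoint pools so
    the triple intersection is exactly the full-evidence set.
    """
    ids = np.array(protein_universe(cfg.n_proteins))
    perm = rng.permutation(len(ids))
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = [str(ids[i]) for i in perm[cursor:cursor + k]]
        cursor += k
        return out

    full = set(take(cfg.n_full_evidence))
    lost = full | set(take(cfg.n_lost_ub - cfg.n_full_evidence))
    inter = full | set(take(cfg.n_interactors - cfg.n_full_evidence))
    ctx_ids = sorted(full) + take(cfg.n_context_genes - cfg.n_full_evidence)
    signs = rng.choice([-1.0, 1.0], size=len(ctx_ids))
    # full-evidence genes behave like the lead substrates: guides enriched
    # when the ligase is already gone (positive effect in sgFBXO11)
    effects = {g: float(s) * cfg.screen.effect for g, s in zip(ctx_ids, signs)}
    for g in full:
        effects[g] = abs(effects[g])
    return lost, inter, effects, full


# ---------------------------------------------------------------------------
# Ubiquitylome stream

def ub_condition_columns(n_replicates: int) -> tuple[list[str], list[str]]:
    ko = [f"KO_rep{r}" for r in range(1, n_replicates + 1)]
    wt = [f"WT_rep{r}" for r in range(1, n_replicates + 1)]
    return ko, wt


def gen_ub_peptides(cfg: SimConfig,
                    rng: np.random.Generator | None = None,
                    lost_set: set[str] | None = None,
                    ) -> tuple[pd.DataFrame, set[str]]:
    """diGly-site intensity table, KO vs WT, with planted lost-Ub proteins.

    Planted proteins have KO/WT mean intensity ratio 2**(-effect) at every
    site; null proteins have ratio 1.  Returns (table, planted protein set).
    """
    cfg.validate()
    u = cfg.ub
    rngs = stream_rngs(cfg.seed)
    if rng is None:
        rng = rngs["ub"]
    if lost_set is None:
        lost_set, _, _, _ = plant_design(cfg, rngs["design"])
    ids = protein_universe(cfg.n_proteins)
    missing = lost_set - set(ids)
    if missing:
        raise ConfigurationError(f"planted proteins outside universe: {sorted(missing)}")

    ko_cols, wt_cols = ub_condition_columns(u.n_replicates)
    rows = []
    for pid in ids:
        k = int(rng.integers(u.sites_min, u.sites_max + 1))
        positions = np.sort(rng.choice(np.arange(1, 801), size=k, replace=False))
        for pos in positions:
            base = u.base_log2_mean + u.base_log2_sd * rng.standard_normal()
            wt = 2.0 ** (base + u.noise_sd * rng.standard_normal(u.n_replicates))
            ko_mu = base - (u.effect if pid in lost_set else 0.0)
            ko = 2.0 ** (ko_mu + u.noise_sd * rng.standard_normal(u.n_replicates))
            row = {"protein_id": pid, "site_position": int(pos),
                   "peptide_key": f"{pid}_K{int(pos)}"}
            row.update({c: v for c, v in zip(ko_cols, ko)})
            row.update({c: v for c, v in zip(wt_cols, wt)})
            rows.append(row)
    return pd.DataFrame(rows), set(lost_set)


# ---------------------------------------------------------------------------
# IP spectral-count stream

def gen_spectral_counts(cfg: SimConfig,
                        rng: np.random.Generator | None = None,
                        interactor_set: set[str] | None = None,
                        ) -> tuple[pd.DataFrame, set[str]]:
    """IP vs IgG spectral counts: multinomial draws over detected proteins.

    Planted interactors have IP proportion = fold x their IgG proportion
    (renormalized); the bait is enriched by ``bait_fold``.
    """
    cfg.validate()
    p = cfg.ip
    rngs = stream_rngs(cfg.seed)
    if rng is None:
        rng = rngs["ip"]
    if interactor_set is None:
        _, interactor_set, _, _ = plant_design(cfg, rngs["design"])
    if p.fold < 1.0:
        raise ConfigurationError("fold for planted interactors must be >= 1")

    ids = protein_universe(cfg.n_proteins)
    planted = sorted(interactor_set)
    others = [i for i in ids if i not in interactor_set]
    n_other = max(0, p.n_detected - len(planted))
    detected = planted + [others[i] for i in
                          rng.choice(len(others), size=min(n_other, len(others)),
                                     replace=False)]
    detected = sorted(detected) + [cfg.bait_id]

    base = rng.dirichlet(np.full(len(detected), p.dirichlet_alpha))
    fold = np.ones(len(detected))
    for i, pid in enumerate(detected):
        if pid in interactor_set:
            fold[i] = p.fold
        elif pid == cfg.bait_id:
            fold[i] = p.bait_fold
    p_ip = base * fold
    p_ip /= p_ip.sum()

    c_igg = rng.multinomial(p.total_igg, base)
    c_ip = rng.multinomial(p.total_ip, p_ip)
    table = pd.DataFrame({"protein_id": detected,
                          "count_ip": c_ip.astype(int),
                          "count_igg": c_igg.astype(int)})
    return table, set(interactor_set)


# ---------------------------------------------------------------------------
# CRISPR screen stream

def screen_column(context: str, timepoint: str, rep: int) -> str:
    return f"{context}_{timepoint}_rep{rep}"


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float
               ) -> np.ndarray:
    """Gamma-Poisson counts with var = mu + a*mu^2; a=0 is deterministic."""
    if dispersion == 0:
        return np.rint(mean).astype(int)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam).astype(int)


def gen_guide_counts(cfg: SimConfig,
                     rng: np.random.Generator | None = None,
                     context_effects: dict[str, float] | None = None,
                     ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Guide read-count matrix for the two-context colony screen.

    Context-dependent genes receive their signed log2 day10/day0 effect
    only in the sgFBXO11 context; all other guide abundances are stable.
    """
    cfg.validate()
    s = cfg.screen
    rngs = stream_rngs(cfg.seed)
    if rng is None:
        rng = rngs["screen"]
    if context_effects is None:
        _, _, context_effects, _ = plant_design(cfg, rngs["design"])

    genes = protein_universe(cfg.n_proteins)
    n_guides = len(genes) * s.guides_per_gene
    guide_ids = [f"{g}_g{j}" for g in genes for j in range(1, s.guides_per_gene + 1)]
    gene_col = np.repeat(genes, s.guides_per_gene)

    day0_mean = 2.0 ** (s.day0_log2_mean + s.day0_log2_sd * rng.standard_normal(n_guides))
    effect = np.array([context_effects.get(g, 0.0) for g in gene_col])

    data: dict[str, np.ndarray] = {}
    for ctx in SCREEN_CONTEXTS:
        lfc = effect if ctx == "sgFBXO11" else np.zeros(n_guides)
        for tp in SCREEN_TIMEPOINTS:
            mu = day0_mean if tp == "day0" else day0_mean * 2.0 ** lfc
            for r in range(1, s.n_replicates + 1):
                data[screen_column(ctx, tp, r)] = _nb_counts(rng, mu, s.dispersion)

    df = pd.DataFrame({"guide_id": guide_ids, "gene_id": gene_col, **data})
    return df, dict(context_effects)


# ---------------------------------------------------------------------------
# LFQ proteome stream

def lfq_sample_columns(n_disease: int, n_healthy: int) -> tuple[list[str], list[str]]:
    dis = [f"MDS_{i:02d}" for i in range(1, n_disease + 1)]
    hc = [f"HC_{i:02d}" for i in range(1, n_healthy + 1)]
    return dis, hc


def gen_lfq_matrix(cfg: SimConfig,
                   network: Iterable[str] | None = None,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[pd.DataFrame, pd.Series, dict[str, float]]:
    """Two-group LFQ proteome with interactome-coherent downregulation.

    ``network`` is the node set to shift down in the disease group
    (defaults to the planted interactor set).  Missing values are absent
    (NaN), never zero.  Returns (matrix, group labels, true log2FC map).
    """
    cfg.validate()
    l = cfg.lfq
    rngs = stream_rngs(cfg.seed)
    if rng is None:
        rng = rngs["lfq"]
    if network is None:
        _, inter, _, _ = plant_design(cfg, rngs["design"])
        nodes = set(inter)
    else:
        nodes = set(getattr(network, "nodes", network))

    base_ids = protein_universe(cfg.n_proteins)
    n_extra = max(0, l.n_proteins - len(base_ids))
    ids = base_ids + [f"Q{i:04d}" for i in range(1, n_extra + 1)]
    ids = ids[:l.n_proteins]

    dis_cols, hc_cols = lfq_sample_columns(l.n_disease, l.n_healthy)
    samples = dis_cols + hc_cols
    groups = pd.Series(["MDS"] * l.n_disease + ["healthy"] * l.n_healthy,
                       index=samples, name="group")

    true_lfc = {pid: -l.network_effect for pid in ids if pid in nodes}
    candidates = [pid for pid in ids if pid not in nodes]
    extra_idx = rng.choice(len(candidates), size=min(l.n_extra_de, len(candidates)),
                           replace=False)
    for i in extra_idx:
        true_lfc[candidates[i]] = float(rng.choice([-1.0, 1.0])) * l.extra_effect

    base = l.base_log2_mean + l.base_log2_sd * rng.standard_normal(len(ids))
    shift = np.array([true_lfc.get(pid, 0.0) for pid in ids])
    log2 = (base[:, None]
            + np.where(np.isin(samples, dis_cols), shift[:, None], 0.0)
            + l.noise_sd * rng.standard_normal((len(ids), len(samples))))
    mat = pd.DataFrame(2.0 ** log2, index=pd.Index(ids, name="protein_id"),
                       columns=samples)
    if l.missing_rate > 0:
        mask = rng.random(mat.shape) < l.missing_rate
        mat = mat.mask(mask)
    return mat, groups, true_lfc


def gen_transcriptome_fc(cfg: SimConfig,
                         rng: np.random.Generator | None = None) -> pd.Series:
    """Independent transcriptome log2FC vector over (a subset of) LFQ ids.

    Drawn independently of the proteome, emulating the observed lack of
    proteome-transcriptome fold-change correlation.
    """
    if rng is None:
        rng = stream_rngs(cfg.seed)["lfq"]
        rng = np.random.default_rng(rng.integers(2 ** 31))  # sub-draw, keeps lfq intact
    base_ids = protein_universe(cfg.n_proteins)
    n_extra = max(0, cfg.lfq.n_proteins - len(base_ids))
    ids = (base_ids + [f"Q{i:04d}" for i in range(1, n_extra + 1)])[:cfg.lfq.n_proteins]
    keep = rng.random(len(ids)) < 0.8
    sel = [i for i, k in zip(ids, keep) if k]
    return pd.Series(rng.standard_normal(len(sel)),
                     index=pd.Index(sel, name="protein_id"), name="log2fc_rna")


# ---------------------------------------------------------------------------
# Interaction-network edge stream

def gen_network_edges(cfg: SimConfig,
                      rng: np.random.Generator | None = None,
                      interactor_set: set[str] | None = None) -> pd.DataFrame:
    """Pre-scored edge table: confident edges within the planted interactome
    (plus the bait hub), low-confidence decoys elsewhere."""
    cfg.validate()
    rngs = stream_rngs(cfg.seed)
    if rng is None:
        rng = rngs["network"]
    if interactor_set is None:
        _, interactor_set, _, _ = plant_design(cfg, rngs["design"])
    inter = sorted(interactor_set)
    rows: list[tuple[str, str, float]] = []
    for pid in inter:  # bait hub: every interactor touches the bait confidently
        rows.append((cfg.bait_id, pid, float(rng.uniform(0.75, 0.99))))
    for i in range(len(inter)):
        for j in range(i + 1, len(inter)):
            u = rng.random()
            if u < 0.3:
                rows.append((inter[i], inter[j], float(rng.uniform(0.72, 0.99))))
            elif u < 0.45:
                rows.append((inter[i], inter[j], float(rng.uniform(0.1, 0.65))))
    ids = protein_universe(cfg.n_proteins)
    for _ in range(cfg.n_decoy_edges):
        a, b = rng.choice(len(ids), size=2, replace=False)
        rows.append((ids[a], ids[b], float(rng.uniform(0.1, 0.69))))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])


# ---------------------------------------------------------------------------
# Splicing stream

def splice_sample_columns(n_group1: int, n_group2: int) -> tuple[list[str], list[str]]:
    g1 = [f"MDS_s{i:02d}" for i in range(1, n_group1 + 1)]
    g2 = [f"HC_s{i:02d}" for i in range(1, n_group2 + 1)]
    return g1, g2


EVENT_TYPES = ("SE", "RI", "A3SS", "A5SS", "MXE")


def gen_splicing_counts(cfg: SimConfig,
                        rng: np.random.Generator | None = None,
                        ) -> tuple["SpliceEventTable", dict[str, float]]:
    """Inclusion/skipping junction counts with planted delta-PSI events.

    Planted events shift group-1 (disease) PSI by +dpsi when the baseline
    is below 0.5 and by -dpsi otherwise, keeping PSI inside [0, 1].
    """
    from .splicing import SpliceEventTable  # local import avoids a cycle
    cfg.validate()
    sp = cfg.splice
    if rng is None:
        rng = stream_rngs(cfg.seed)["splice"]

    genes = protein_universe(cfg.n_proteins)
    event_ids = [f"E{i:04d}" for i in range(1, sp.n_events + 1)]
    gene_assign = [genes[i] for i in rng.integers(0, len(genes), size=sp.n_events)]
    etypes = [EVENT_TYPES[i % len(EVENT_TYPES)] for i in range(sp.n_events)]
    base_psi = rng.uniform(sp.psi_min, sp.psi_max, size=sp.n_events)

    planted_idx = rng.choice(sp.n_events, size=sp.n_planted, replace=False)
    dpsi = np.zeros(sp.n_events)
    for i in planted_idx:
        dpsi[i] = sp.dpsi if base_psi[i] < 0.5 else -sp.dpsi

    g1, g2 = splice_sample_columns(sp.n_group1, sp.n_group2)
    samples = g1 + g2
    psi = np.tile(base_psi[:, None], (1, len(samples)))
    psi[:, :len(g1)] = np.clip(psi[:, :len(g1)] + dpsi[:, None], 0.0, 1.0)

    depth = rng.poisson(sp.depth, size=(sp.n_events, len(samples)))
    inc = rng.binomial(depth, psi)
    skp = depth - inc

    meta = pd.DataFrame({"gene": gene_assign, "event_type": etypes,
                         "len_inclusion": 2, "len_skipping": 1},
                        index=pd.Index(event_ids, name="event_id"))
    inclusion = pd.DataFrame(inc, index=meta.index, columns=samples)
    skipping = pd.DataFrame(skp, index=meta.index, columns=samples)
    truth = {event_ids[i]: float(dpsi[i]) for i in planted_idx}
    table = SpliceEventTable(meta=meta, inclusion=inclusion, skipping=skipping)
    return table, truth


def gen_expression_vector(cfg: SimConfig,
                          rng: np.random.Generator | None = None) -> pd.Series:
    """Per-sample FBXO11 expression used for quartile grouping: lower in disease."""
    sp = cfg.splice
    if rng is None:
        base = stream_rngs(cfg.seed)["splice"]
        rng = np.random.default_rng(base.integers(2 ** 31))
    g1, g2 = splice_sample_columns(sp.n_group1, sp.n_group2)
    expr = np.concatenate([8.0 + rng.standard_normal(len(g1)),
                           10.0 + rng.standard_normal(len(g2))])
    return pd.Series(expr, index=g1 + g2, name="FBXO11_expression")


# ---------------------------------------------------------------------------
# Imaging stream

def ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                 axes: tuple[float, float], angle: float = 0.0) -> np.ndarray:
    """Boolean raster of a filled ellipse over pixel centers.

    ``center`` is (row, col); ``axes`` are semi-axes (a along the rotated
    col direction, b perpendicular); ``angle`` in radians, measured from
    the +col axis toward +row.
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    y = rr - center[0]
    x = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    xr = x * ca + y * sa
    yr = -x * sa + y * ca
    a, b = axes
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def _place_objects(icfg: ImageSimConfig, rng: np.random.Generator
                   ) -> list[dict[str, Any]]:
    h, w = icfg.shape
    cy, cx = h / 2.0, w / 2.0
    A, B = icfg.nucleus_axes
    placed: list[dict[str, Any]] = []
    tries = 0
    while len(placed) < icfg.n_objects and tries < 5000:
        tries += 1
        major = rng.uniform(*icfg.object_major_range)
        minor = major * rng.uniform(*icfg.elongation_range)
        angle = rng.uniform(0.0, np.pi)
        margin = major + 3.0
        oy = cy + rng.uniform(-(B - margin), B - margin)
        ox = cx + rng.uniform(-(A - margin), A - margin)
        if ((ox - cx) / (A - margin)) ** 2 + ((oy - cy) / (B - margin)) ** 2 > 1.0:
            continue
        ok = True
        for o in placed:
            d = np.hypot(oy - o["center"][0], ox - o["center"][1])
            if d < major + o["axes"][0] + 4.0:
                ok = False
                break
        if ok:
            placed.append({"center": (float(oy), float(ox)),
                           "axes": (float(major), float(minor)),
                           "angle": float(angle)})
    if len(placed) < icfg.n_objects:
        raise ConfigurationError("could not place nucleolar objects; "
                                 "reduce count or size")
    return placed


def gen_nucleus_images(icfg: ImageSimConfig,
                       rng: np.random.Generator,
                       ) -> tuple[list[np.ndarray], list[list[dict[str, Any]]]]:
    """Synthesize (n_images) 3-channel stacks (DAPI, NPM1, FBXO11).

    DAPI: filled nucleus ellipse.  NPM1: nucleoplasmic base + a smooth
    gradient + k bright elliptical objects.  FBXO11: coupled to the NPM1
    fluctuation in the dim compartment only.  Gaussian noise everywhere.
    Returns (stacks, per-image planted-object records).
    """
    icfg.validate()
    h, w = icfg.shape
    stacks: list[np.ndarray] = []
    objects: list[list[dict[str, Any]]] = []
    for _ in range(icfg.n_images):
        cy = h / 2.0 + rng.uniform(-5, 5)
        cx = w / 2.0 + rng.uniform(-5, 5)
        nuc = ellipse_mask((h, w), (cy, cx), icfg.nucleus_axes)

        dapi = np.full((h, w), 20.0)
        dapi[nuc] = icfg.dapi_level

        rr, cc = np.mgrid[0:h, 0:w]
        grad = (icfg.gradient_amplitude
                * ((cc - cx) / max(icfg.nucleus_axes) + (rr - cy) / max(icfg.nucleus_axes))
                / 2.0)
        npm1 = np.full((h, w), 20.0)
        npm1[nuc] = icfg.npm1_dim_level + grad[nuc]

        objs = _place_objects(icfg, rng)
        obj_mask = np.zeros((h, w), dtype=bool)
        for o in objs:
            m = ellipse_mask((h, w), o["center"], o["axes"], o["angle"])
            obj_mask |= m
        npm1[obj_mask] = icfg.npm1_bright_level

        fb = np.full((h, w), 20.0)
        dim = nuc & ~obj_mask
        fb[nuc] = icfg.fbxo11_base
        fb[dim] += icfg.fbxo11_coupling * (npm1[dim] - icfg.npm1_dim_level)
        fb[obj_mask] += rng.normal(0.0, 60.0, size=int(obj_mask.sum()))

        stack = np.stack([dapi, npm1, fb])
        if icfg.noise_sd > 0:
            stack = stack + rng.normal(0.0, icfg.noise_sd, size=stack.shape)
        stacks.append(np.clip(stack, 0.0, 65535.0))
        objects.append(objs)
    return stacks, objects


# ---------------------------------------------------------------------------
# Bundle

@dataclass
class SimBundle:
    """All generated streams plus the aggregated ground truth."""

    ub_table: pd.DataFrame
    spectral_counts: pd.DataFrame
    guide_counts: pd.DataFrame
    lfq_matrix: pd.DataFrame
    lfq_groups: pd.Series
    transcriptome_fc: pd.Series
    splice: Any                      # SpliceEventTable
    expression: pd.Series
    network_edges: pd.DataFrame
    images_control: list[np.ndarray]
    images_fbxo11_low: list[np.ndarray]
    truth: SimTruth


def simulate_all(cfg: SimConfig) -> SimBundle:
    """Generate every stream from one config with coordinated planted sets."""
    cfg.validate()
    rngs = stream_rngs(cfg.seed)
    lost, inter, ctx_effects, full = plant_design(cfg, rngs["design"])

    ub_table, _ = gen_ub_peptides(cfg, rng=rngs["ub"], lost_set=lost)
    sc_table, _ = gen_spectral_counts(cfg, rng=rngs["ip"], interactor_set=inter)
    guides, _ = gen_guide_counts(cfg, rng=rngs["screen"], context_effects=ctx_effects)
    lfq, groups, true_lfc = gen_lfq_matrix(cfg, network=inter, rng=rngs["lfq"])
    rna_fc = gen_transcriptome_fc(cfg, rng=np.random.default_rng(
        rngs["lfq"].integers(2 ** 31)))
    splice, splice_truth = gen_splicing_counts(cfg, rng=rngs["splice"])
    expr = gen_expression_vector(cfg, rng=np.random.default_rng(
        rngs["splice"].integers(2 ** 31)))
    edges = gen_network_edges(cfg, rng=rngs["network"], interactor_set=inter)
    img_c, obj_c = gen_nucleus_images(cfg.image_control, rngs["image_control"])
    img_l, obj_l = gen_nucleus_images(cfg.image_fbxo11_low, rngs["image_fbxo11_low"])

    truth = SimTruth(
        lost_ub_proteins=lost,
        interactors=inter,
        context_genes=ctx_effects,
        de_proteins=true_lfc,
        splice_events=splice_truth,
        objects_per_image={"control": obj_c, "fbxo11_low": obj_l},
        full_evidence=full,
    )
    return SimBundle(
        ub_table=ub_table, spectral_counts=sc_table, guide_counts=guides,
        lfq_matrix=lfq, lfq_groups=groups, transcriptome_fc=rna_fc,
        splice=splice, expression=expr, network_edges=edges,
        images_control=img_c, images_fbxo11_low=img_l, truth=truth,
    )
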