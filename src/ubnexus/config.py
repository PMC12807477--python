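"""Configuration objects for the synthetic benchmark and the pipeline.

Every tunable of the generators and of the analysis stages lives in a
dataclass here, so a run is fully described by one JSON-serializable
object.  Defaults encode the study conditions the pipeline emulates
(replicate counts, sequencing/MS depths, effect sizes, thresholds).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any


class ConfigurationError(ValueError):
    """Raised when a configuration value is outside its valid range."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass
class UbSimConfig:
    """diGly-site peptide intensities, KO vs WT."""

    n_replicates: int = 3
    sites_min: int = 1
    sites_max: int = 3
    base_log2_mean: float = 20.0   # log2 intensity of a typical site (~1e6)
    base_log2_sd: float = 2.0
    noise_sd: float = 0.25         # replicate-to-replicate noise, log2 scale
    effect: float = 1.5            # planted sites: KO/WT mean ratio = 2**(-effect)

    def validate(self) -> None:
        _require(self.n_replicates >= 1, "ub: n_replicates must be >= 1")
        _require(1 <= self.sites_min <= self.sites_max, "ub: bad site range")
        _require(self.noise_sd >= 0, "ub: noise_sd must be >= 0")


@dataclass
class IpSimConfig:
    """Bait IP vs IgG spectral counts (multinomial over detected proteins)."""

    n_detected: int = 120
    total_ip: int = 20000
    total_igg: int = 20000
    fold: float = 8.0              # IP proportion multiplier for planted interactors
    bait_fold: float = 50.0        # the bait itself is heavily enriched in its own IP
    dirichlet_alpha: float = 5.0   # spread of baseline abundances

    def validate(self) -> None:
        _require(self.n_detected >= 1, "ip: n_detected must be >= 1")
        _require(self.total_ip >= 1 and self.total_igg >= 1, "ip: totals must be >= 1")
        _require(self.fold >= 1.0, "ip: fold for planted interactors must be >= 1")
        _require(self.bait_fold >= 1.0, "ip: bait_fold must be >= 1")


@dataclass
class ScreenSimConfig:
    """sgRNA colony-screen counts: day0/day10 x {sgCTRL, sgFBXO11} x replicates."""

    guides_per_gene: int = 6
    n_replicates: int = 2
    day0_log2_mean: float = 9.0    # ~512 reads per guide at day 0
    day0_log2_sd: float = 0.5
    dispersion: float = 0.05       # NB dispersion a: var = mu + a*mu^2; 0 => deterministic
    effect: float = 2.0            # log2(day10/day0) applied in the sgFBXO11 context

    def validate(self) -> None:
        _require(self.guides_per_gene >= 2, "screen: need >= 2 guides per gene")
        _require(self.n_replicates >= 1, "screen: n_replicates must be >= 1")
        _require(self.dispersion >= 0, "screen: dispersion must be >= 0")


@dataclass
class LfqSimConfig:
    """Two-group label-free proteome matrix with network-coherent downregulation."""

    n_proteins: int = 800
    n_disease: int = 13
    n_healthy: int = 6
    base_log2_mean: float = 25.0
    base_log2_sd: float = 2.0
    noise_sd: float = 0.5          # within-group biological+technical noise, log2
    network_effect: float = 1.0    # log2 down-shift of interactome nodes in disease
    n_extra_de: int = 20
    extra_effect: float = 1.0
    missing_rate: float = 0.1      # completely-at-random missingness

    def validate(self) -> None:
        _require(self.n_proteins >= 1, "lfq: n_proteins must be >= 1")
        _require(self.n_disease >= 2 and self.n_healthy >= 2, "lfq: >= 2 samples per group")
        _require(0 <= self.missing_rate < 1, "lfq: missing_rate in [0, 1)")
        _require(self.noise_sd >= 0, "lfq: noise_sd must be >= 0")


@dataclass
class SpliceSimConfig:
    """Inclusion/skipping junction counts with planted delta-PSI events."""

    n_events: int = 300
    n_planted: int = 20
    dpsi: float = 0.3
    n_group1: int = 10             # disease samples
    n_group2: int = 10             # healthy controls
    depth: float = 100.0           # mean junction reads per event per sample
    psi_min: float = 0.2
    psi_max: float = 0.6

    def validate(self) -> None:
        _require(self.n_events >= 1, "splice: n_events must be >= 1")
        _require(0 <= self.n_planted <= self.n_events, "splice: n_planted out of range")
        _require(self.depth > 0, "splice: depth must be > 0")
        _require(0 <= self.psi_min <= self.psi_max <= 1, "splice: bad psi range")


@dataclass
class ImageSimConfig:
    """Nucleus images: DAPI ellipse, NPM1-bright nucleolar objects, FBXO11 channel."""

    n_images: int = 4
    shape: tuple[int, int] = (256, 256)
    nucleus_axes: tuple[float, float] = (90.0, 70.0)   # semi-axes, px
    n_objects: int = 3
    object_major_range: tuple[float, float] = (14.0, 22.0)   # semi-major axis, px
    elongation_range: tuple[float, float] = (0.45, 0.65)     # semi-minor / semi-major
    dapi_level: float = 3000.0
    npm1_dim_level: float = 800.0
    npm1_bright_level: float = 3000.0
    gradient_amplitude: float = 120.0   # smooth nucleoplasmic NPM1 variation
    fbxo11_base: float = 500.0
    fbxo11_coupling: float = 0.8        # FBXO11 ~ NPM1 coupling in the dim compartment
    noise_sd: float = 30.0

    def __post_init__(self) -> None:
        self.shape = tuple(self.shape)  # type: ignore[assignment]
        self.nucleus_axes = tuple(self.nucleus_axes)  # type: ignore[assignment]
        self.object_major_range = tuple(self.object_major_range)  # type: ignore[assignment]
        self.elongation_range = tuple(self.elongation_range)  # type: ignore[assignment]

    def validate(self) -> None:
        _require(self.n_images >= 1, "image: n_images must be >= 1")
        _require(self.n_objects >= 0, "image: n_objects must be >= 0")
        _require(self.noise_sd >= 0, "image: noise_sd must be >= 0")
        _require(min(self.shape) >= 32, "image: grid too small")
        lo, hi = self.elongation_range
        _require(0 < lo <= hi <= 1, "image: elongation must be in (0, 1]")

    @staticmethod
    def control_like() -> "ImageSimConfig":
        """Few, larger, elongated nucleolar objects (intact-ligase morphology)."""
        return ImageSimConfig()

    @staticmethod
    def fbxo11_low_like() -> "ImageSimConfig":
        """More, smaller, rounder objects (ligase-depleted morphology)."""
        return ImageSimConfig(
            n_objects=6,
            object_major_range=(8.0, 12.0),
            elongation_range=(0.85, 0.98),
        )


@dataclass
class SimConfig:
    """Top-level synthetic-benchmark configuration.

    A single seed drives all streams through documented per-stream
    substreams, so regenerating one stream never perturbs another.
    """

    seed: int = 0
    n_proteins: int = 200          # shared protein/gene universe of the 3 evidence streams
    n_lost_ub: int = 20
    n_interactors: int = 15
    n_context_genes: int = 10
    n_full_evidence: int = 2       # planted in all three streams; the true substrates
    n_decoy_edges: int = 40        # low-confidence network edges
    bait_id: str = "FBXO11"
    ub: UbSimConfig = field(default_factory=UbSimConfig)
    ip: IpSimConfig = field(default_factory=IpSimConfig)
    screen: ScreenSimConfig = field(default_factory=ScreenSimConfig)
    lfq: LfqSimConfig = field(default_factory=LfqSimConfig)
    splice: SpliceSimConfig = field(default_factory=SpliceSimConfig)
    image_control: ImageSimConfig = field(default_factory=ImageSimConfig.control_like)
    image_fbxo11_low: ImageSimConfig = field(default_factory=ImageSimConfig.fbxo11_low_like)

    def validate(self) -> None:
        _require(self.n_proteins >= 1, "n_proteins must be >= 1")
        n_extra = (self.n_lost_ub - self.n_full_evidence) \
            + (self.n_interactors - self.n_full_evidence) \
            + (self.n_context_genes - self.n_full_evidence)
        _require(self.n_full_evidence <= min(self.n_lost_ub, self.n_interactors,
                                             self.n_context_genes),
                 "n_full_evidence exceeds a planted-set size")
        _require(self.n_full_evidence + n_extra <= self.n_proteins,
                 "planted sets do not fit in the protein universe")
        for sub in (self.ub, self.ip, self.screen, self.lfq, self.splice,
                    self.image_control, self.image_fbxo11_low):
            sub.validate()


@dataclass
class Thresholds:
    """All analysis cutoffs, aggregated."""

    ub_log2fc: float = 0.5          # |log2FC| cutoff for differential diGly sites
    ip_alpha: float = 0.05          # G-test p cutoff of the significance box
    ip_fold: float = 1.5            # fold-enrichment cutoff of the significance box
    network_confidence: float = 0.7  # medium-confidence edge cutoff
    screen_alpha: float = 0.05      # paired-test cutoff for context dependence
    de_p: float = 0.05              # proteome DE p cutoff
    de_log2fc: float = 0.5          # proteome DE |log2FC| cutoff
    splice_fdr: float = 0.05
    splice_p: float = 0.05
    splice_dpsi: float = 0.15

    def validate(self) -> None:
        for name in ("ip_alpha", "screen_alpha", "de_p", "splice_fdr", "splice_p"):
            v = getattr(self, name)
            _require(0 < v < 1, f"threshold {name} must be in (0, 1)")
        _require(0 <= self.network_confidence <= 1, "network_confidence in [0, 1]")
        _require(self.ub_log2fc >= 0 and self.de_log2fc >= 0, "FC cutoffs must be >= 0")
        _require(0 <= self.splice_dpsi <= 1, "splice_dpsi in [0, 1]")
        _require(self.ip_fold >= 0, "ip_fold must be >= 0")


@dataclass
class RunConfig:
    """End-to-end pipeline run: inputs (simulated or on disk) + thresholds."""

    outdir: str = "results/run"
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_perm: int = 1000              # GSEA permutations
    inputs: dict[str, str] = field(default_factory=dict)  # paths when simulate=False

    def validate(self) -> None:
        _require(self.n_perm >= 1, "n_perm must be >= 1")
        self.sim.validate()
        self.thresholds.validate()


def _to_jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    return obj


def _from_dict(cls: type, d: dict[str, Any]) -> Any:
    kwargs: dict[str, Any] = {}
    for f in fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if is_dataclass(f.type if isinstance(f.type, type) else None) and isinstance(v, dict):
            kwargs[f.name] = _from_dict(f.type, v)  # type: ignore[arg-type]
        else:
            kwargs[f.name] = v
    return cls(**kwargs)


_NESTED = {
    "ub": UbSimConfig, "ip": IpSimConfig, "screen": ScreenSimConfig,
    "lfq": LfqSimConfig, "splice": SpliceSimConfig,
    "image_control": ImageSimConfig, "image_fbxo11_low": ImageSimConfig,
    "sim": SimConfig, "thresholds": Thresholds,
}


def config_to_dict(cfg: Any) -> dict[str, Any]:
    return _to_jsonable(cfg)


def config_from_dict(cls: type, d: dict[str, Any]) -> Any:
    kwargs: dict[str, Any] = {}
    for f in fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if f.name in _NESTED and isinstance(v, dict):
            v = config_from_dict(_NESTED[f.name], v)
        kwargs[f.name] = v
    obj = cls(**kwargs)
    return obj


def save_config(cfg: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config_to_dict(cfg), indent=2, sort_keys=True))


def load_run_config(path: str | Path) -> RunConfig:
    d = json.loads(Path(path).read_text())
    cfg = config_from_dict(RunConfig, d)
    cfg.validate()
    return cfg


def load_sim_config(path: str | Path) -> SimConfig:
    d = json.loads(Path(path).read_text())
    cfg = config_from_dict(SimConfig, d)
    cfg.validate()
    return cfg
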