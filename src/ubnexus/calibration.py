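"""Null-calibration simulations: type-I error rates of every test stage.

Each function builds null-configured synthetic streams (no planted
effects) through the package's own generators, runs the corresponding
analysis stage, and returns the fraction of p-values below alpha
together with the number of independent null units — so the caller can
check the rate against alpha with a binomial tolerance.  FC-filtered
calls (significance box, volcano significance) are sub-alpha under the
null by construction; calibration therefore targets the p-values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import ip_enrichment, proteome, screen, splicing
from .config import SimConfig


@dataclass
class NullRate:
    rate: float
    n_units: int
    alpha: float

    @property
    def tolerance(self) -> float:
        """Three binomial standard errors at the nominal alpha."""
        return 3.0 * np.sqrt(self.alpha * (1 - self.alpha) / self.n_units)

    @property
    def within(self) -> bool:
        return abs(self.rate - self.alpha) <= self.tolerance


def null_ip_rate(seed: int, n_streams: int = 8, n_proteins: int = 125,
                 depth: int = 50000, alpha: float = 0.05) -> NullRate:
    """G-test positive rate with fold = 1 everywhere (no interactors)."""
    rng = np.random.default_rng(seed)
    positives = total = 0
    for _ in range(n_streams):
        p = rng.dirichlet(np.full(n_proteins, 50.0))
        c_ip = rng.multinomial(depth, p)
        c_igg = rng.multinomial(depth, p)
        _, pvals = ip_enrichment.g_test(c_ip, c_igg, depth, depth)
        positives += int(np.sum(pvals < alpha))
        total += n_proteins
    return NullRate(rate=positives / total, n_units=total, alpha=alpha)


def null_screen_rate(seed: int, n_streams: int = 10, n_genes: int = 60,
                     alpha: float = 0.05) -> NullRate:
    """Paired context-test positive rate with no context-dependent genes."""
    positives = total = 0
    for k in range(n_streams):
        cfg = SimConfig(seed=seed + k, n_proteins=n_genes, n_lost_ub=2,
                        n_interactors=2, n_context_genes=2, n_full_evidence=2)
        from .synthetic import gen_guide_counts
        counts, _ = gen_guide_counts(cfg, context_effects={})
        res = screen.analyze_screen(counts, n_replicates=cfg.screen.n_replicates)
        positives += int((res["p_value"] < alpha).sum())
        total += len(res)
    return NullRate(rate=positives / total, n_units=total, alpha=alpha)


def null_de_rate(seed: int, n_streams: int = 2, n_proteins: int = 500,
                 alpha: float = 0.05) -> NullRate:
    """Welch-test positive rate on a no-effect two-group LFQ matrix."""
    positives = total = 0
    for k in range(n_streams):
        cfg = SimConfig(seed=seed + k)
        cfg.lfq.n_proteins = n_proteins
        cfg.lfq.network_effect = 0.0
        cfg.lfq.n_extra_de = 0
        cfg.lfq.missing_rate = 0.0
        from .synthetic import gen_lfq_matrix
        mat, groups, _ = gen_lfq_matrix(cfg, network=set())
        log2m = proteome.preprocess(mat, groups)
        de = proteome.differential_proteins(log2m, groups)
        tested = de[de["skipped_reason"] == ""]
        positives += int((tested["p_value"] < alpha).sum())
        total += len(tested)
    return NullRate(rate=positives / total, n_units=total, alpha=alpha)


def null_splice_rate(seed: int, n_events: int = 1000,
                     alpha: float = 0.05) -> NullRate:
    """Binomial-LRT positive rate with no planted delta-PSI events."""
    cfg = SimConfig(seed=seed)
    cfg.splice.n_events = n_events
    cfg.splice.n_planted = 0
    from .synthetic import gen_splicing_counts, splice_sample_columns
    table, _ = gen_splicing_counts(cfg)
    g1, g2 = splice_sample_columns(cfg.splice.n_group1, cfg.splice.n_group2)
    res = splicing.event_test(table, g1, g2)
    tested = res[res["skipped_reason"] == ""]
    rate = float((tested["p_value"] < alpha).mean())
    return NullRate(rate=rate, n_units=len(tested), alpha=alpha)


def all_null_rates(seed: int) -> dict[str, NullRate]:
    """The four stage calibrations, on disjoint seed offsets."""
    return {
        "ip_g_test": null_ip_rate(seed),
        "screen_paired_test": null_screen_rate(seed + 1000),
        "proteome_welch_test": null_de_rate(seed + 2000),
        "splice_lrt": null_splice_rate(seed + 3000),
    }
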