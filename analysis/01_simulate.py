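#!/usr/bin/env python
"""Generate the synthetic benchmark and write every input stream.

All downstream analysis scripts re-derive the same benchmark
deterministically from BENCH_SEED, so they can run independently; this
script materializes the streams on disk for inspection.
"""
from pathlib import Path

from ubnexus.config import RunConfig, SimConfig
from ubnexus.pipeline import write_inputs
from ubnexus.synthetic import simulate_all

BENCH_SEED = 11
OUTDIR = Path("results/analysis")


def main() -> None:
    cfg = SimConfig(seed=BENCH_SEED)
    bundle = simulate_all(cfg)
    write_inputs(bundle, OUTDIR, RunConfig(outdir=str(OUTDIR), sim=cfg))
    t = bundle.truth
    print(f"wrote input streams under {OUTDIR / 'inputs'}")
    print(f"diGly sites: {len(bundle.ub_table)} rows, "
          f"{len(t.lost_ub_proteins)} proteins with planted lost ubiquitylation")
    print(f"IP table: {len(bundle.spectral_counts)} proteins, "
          f"{len(t.interactors)} planted interactors")
    print(f"screen: {len(bundle.guide_counts)} guides, "
          f"{len(t.context_genes)} planted context-dependent genes")
    print(f"LFQ matrix: {bundle.lfq_matrix.shape[0]} proteins x "
          f"{bundle.lfq_matrix.shape[1]} samples")
    print(f"splicing: {len(bundle.splice.meta)} events, "
          f"{len(t.splice_events)} planted delta-PSI events")
    print(f"images: {len(bundle.images_control)} control + "
          f"{len(bundle.images_fbxo11_low)} ligase-low nuclei")
    print(f"planted full-evidence substrates: {sorted(t.full_evidence)}")


if __name__ == "__main__":
    main()
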