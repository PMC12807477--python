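# Methods

This note documents the models behind each pipeline stage, the
synthetic benchmark that stands in for the original data streams, the
numerical choices, and what the tests do and do not establish.

## Evidence streams and their statistics

### Differential ubiquitylome

Input: a diGly-site peptide intensity table with replicate columns for
KO and WT. Replicates are collapsed by the arithmetic mean before the
ratio (the simplest estimator consistent with a single fold change per
site), and `log2FC = log2((mean_KO + pc)/(mean_WT + pc))` with a default
pseudocount of 1 intensity unit guarding all-zero rows. The
differential-site cutoff `|log2FC| >= 0.5` is interpreted on the log2
scale (the fold-change heatmap axis convention); it is a configurable
threshold, and a protein is flagged `lost_ub` when at least one of its
sites reaches `log2FC <= -0.5`.

### IP enrichment (G test)

The spectral-count G test compares a protein's counts in the bait IP and
the IgG control against expected counts formed from the two runs'
**total** spectral counts (per-run sampling depth), not from the row
marginals of a 2x2 table — the standard spectral-count formulation,
robust to depth imbalance. This 2-cell G equals the binomial LRT of the
IP fraction against the depth ratio; the tests verify that equivalence
against a log-pmf oracle. No Williams or continuity correction is
applied (1 df; counts can be small — a documented limitation). The
fold-enrichment pseudocount (0.5) applies to the ratio only, never to G.
Multiple-testing correction is off by default for the significance box
(raw p < 0.05 with fold > 1.5, following the box convention); BH
q-values are always emitted and an `adjust` flag switches the box to q.

### Screen context test

Guide counts are CPM-normalized per sample; each guide's
`log2FC(day10/day0)` is computed per replicate (pseudocount 1 CPM) and
averaged at the FC level. Genes are summarized by the median guide FC
per context (robust to single bad guides), and the matched guide FCs are
compared between contexts with a two-tailed paired t test, BH-corrected
across genes. Zero-variance difference vectors yield p = 1 with a
`degenerate` flag rather than an unstable t. A significant gene's class
is named by the context with the larger absolute median FC and the sign
of that median (enriched/depleted in sgCTRL/sgFBXO11). Robust-rank
aggregation is deliberately not reimplemented; the paired-FC contrast is
the statistic of interest here.

### Integration

Profiles outer-join the three streams on a single protein/gene id
namespace (an explicit mapping table is accepted; unmapped ids are kept
and flagged). Nomination is the strict triple intersection. The rank
score — `z(-min site log2FC) + z(G) + z(|mean paired diff|)` — is an
artifact-defined ordering aid, not part of the criterion.

### Proteome stage

Quantities are log2-transformed; proteins sparse in **both** groups
(present in < 50% of samples per group) are dropped; columns are
median-centered. Missing values stay missing — no imputation anywhere;
tests use available values only. Differential analysis is a per-protein
Welch t on available values with BH q; volcano significance is raw
p < 0.05 with |log2FC| > 0.5 (q is also emitted). PCA uses the top 50%
most variable among fully quantified proteins (complete rows only, so
the decomposition needs no imputation), row-centered, via SVD.
Clustering uses the top 400 proteins by differential p-value, row
z-scored, with 1 - Pearson distance and average linkage for both
samples and rows (the common default of the clustering web tools this
emulates); row clusters are cut at a configurable k. Network projection
attaches per-protein log2FC as node attributes, flagging unquantified
nodes.

GSEA ranks proteins by the Welch t statistic (a documented choice; the
ranking metric is configurable) and computes the weighted-KS running
sum with weight 1. The null is gene-label permutation of set membership
(sample permutation would be underpowered at 6 vs 13 samples);
`NES = ES / mean(|ES_null| of matching sign)` and the p-value is the
one-sided tail **within the matching-sign null**, `(1+k)/(n_same+1)` —
the standard convention, which keeps null p-values uniform; normalizing
by all permutations instead would compress p into (0, ~0.5]. ES is
invariant to monotone transforms of the ranking metric only in the
unweighted case (weight 0); with weight 1 it depends on metric
magnitudes, and the property tests reflect that.

### Splicing

`PSI = I/(I+S)` per sample, undefined when I+S = 0; optional
length-normalized form `(I/lI)/((I/lI)+(S/lS))` (off by default —
junction counting). The group test pools counts within each group and
applies a binomial LRT against a shared inclusion proportion. This is a
stated substitution for the hierarchical replicate likelihood of the
rMATS framework: the contribution in scope is the threshold-based event
selection (FDR < 0.05, p < 0.05, |dPSI| > 0.15), not that likelihood.
Pooling ignores between-sample overdispersion, so its p-values are
anticonservative on biological replicates — acceptable here because the
benchmark generates binomial counts, and documented as the main caveat
for real data. Expression quartile grouping assigns samples >= Q3 to
the high group and <= Q1 to the low group (inclusive boundaries, linear
interpolation for the quantiles); an all-tied vector is degenerate and
yields empty groups.

### Imaging

Nuclei are segmented by global Otsu on DAPI with hole filling and a
minimum area (default 500 px). "Relative thresholding within nuclei" is
implemented as per-ROI Otsu on the NPM1 values, giving an exact
bright/dim partition of each nucleus; the method is pluggable. Object
morphometry uses connected components (8-connectivity), Crofton
perimeter, circularity `4*pi*A/P^2` clamped at 1.0 (digital perimeter
underestimation can push the ratio slightly above 1), and Feret
diameters from a caliper sweep over the convex hull at 1° angular
resolution — the width error of the sweep is bounded by
`maxFeret * (1 - cos(0.5°)) < 4e-5 * maxFeret`, far below the
discretization error of rasterized shapes. Feret diameters are measured
on pixel centers. Colocalization is plain Pearson on pixel pairs within
each compartment mask (>= 3 pixels and nonzero variance required).
Per-nucleus SD is the population standard deviation; MFI normalization,
when used for "relative" reporting, divides by the control-group mean
(a configuration choice).

## The synthetic benchmark

The generators encode the study conditions the pipeline expects:

- **Universe**: 200 proteins/genes shared by the three evidence
  streams; 20 lost-Ub proteins, 15 interactors, 10 context-dependent
  genes, of which 2 **full-evidence** proteins are planted in all three
  streams. The remaining planted ids are drawn from disjoint pools so
  the triple intersection is exactly the full-evidence pair — the
  end-to-end recovery target is unambiguous by construction.
- **Ubiquitylome**: 1-3 sites per protein, log-normal base intensities
  (log2 mean 20, sd 2), replicate noise sd 0.25 (log2), 3 replicates;
  planted proteins have KO/WT mean ratio `2^-1.5` at every site.
- **Spectral counts**: Dirichlet baseline proportions over ~120
  detected proteins, multinomial draws of 20,000 counts per run;
  planted interactors have IP proportion = 8x baseline (renormalized);
  the bait is enriched 50x.
- **Screen**: 6 guides/gene, 2 replicates, day-0 means ~512 reads
  (log-normal), gamma-Poisson counts with dispersion 0.05; planted
  genes get a signed log2 effect of 2 at day 10 in the sgFBXO11 context
  only. Dispersion 0 is a special deterministic regime (counts = rounded
  means) used by exactness tests; there is no Poisson-only intermediate.
- **LFQ proteome**: 800 proteins (the 200-universe plus extras), 13
  disease vs 6 healthy samples, within-group noise sd 0.5 (log2);
  interactome nodes shifted down 1.0 log2 unit in disease plus 20 other
  DE proteins (+/-1.0); 10% missing completely at random, encoded as
  absent (never zero) because label-free missingness must be visible to
  the presence filters. An independent standard-normal transcriptome
  log2FC vector emulates the absence of transcript-level correlation.
- **Splicing**: 300 events across the five canonical types, baseline
  PSI ~ U(0.2, 0.6), per-sample depth Poisson(100), binomial inclusion
  counts; 20 planted events shift disease PSI by +/-0.3 (sign chosen to
  stay inside [0, 1]).
- **Images**: 256x256 px, one elliptical nucleus (semi-axes 90x70),
  nucleoplasmic NPM1 800 with a smooth +/-120 gradient, bright objects
  at 3000, Gaussian noise sd 30. The control-like condition plants 3
  elongated objects (semi-major 14-22 px, elongation 0.45-0.65); the
  ligase-depleted condition plants 6 smaller, rounder objects (8-12 px,
  0.85-0.98). The FBXO11 channel tracks the NPM1 fluctuation in the dim
  compartment only (coupling 0.8), so dim-compartment colocalization
  exceeds bright-compartment colocalization by construction.

One global seed expands into per-stream substreams via
`SeedSequence.spawn` in a fixed, documented order (design, ub, ip,
screen, lfq, splice, image_control, image_fbxo11_low, network), so
adding a stream never perturbs existing ones, and identical config +
seed is bit-identical everywhere.

What the generators do **not** emulate: peptide-level missingness
structure (MNAR intensity dependence), guide off-target effects and
copy-number artifacts, overdispersed junction counts, optics (PSF,
chromatic shift, uneven illumination), and correlated multi-nucleus
fields. Passing tests therefore demonstrate correctness of the
statistics and the plumbing under the stated error models — not
robustness to every artifact of real acquisitions.

## Problem sizes and runtime

The default benchmark (200-protein universe, 800-protein proteome, 300
events, 8 images) runs end to end in a few seconds; the null
calibrations use 600-1000 independent null units per stage (8x125
proteins for the G test, 10x60 genes for the screen, 2x500 proteins for
the proteome, 1000 events for splicing), chosen so the three-binomial-SE
tolerance is meaningful (~+/-0.02 around alpha = 0.05) while the whole
suite stays fast.

## Known limitations

- The pooled splicing LRT is anticonservative under biological
  overdispersion (see above).
- The G test with very low counts relies on the chi-square asymptotics;
  no small-sample correction is applied.
- Circularity clamping hides genuinely super-circular digitization
  artifacts; uncapped values are recoverable from area and perimeter.
- The rank score for nominations is a heuristic composite; only the
  intersection criterion is load-bearing.
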