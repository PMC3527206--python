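# Methods

This note documents the models, parameter choices and numerical
conventions behind `methdomains`: what the synthetic-methylome generator
emulates, how the analysis stages are defined, and where the design was
genuinely open and a choice had to be made.

## Coordinates and formats

All in-memory coordinates are 0-based half-open.  BED and bedGraph output
is 0-based half-open; SAM output is 1-based.  A CpG dyad is addressed by
the position of its top-strand C; the bottom-strand record of the same
dyad sits at position + 1.  Call tables are TSV with columns
`chrom, pos0, strand, context, n_meth, n_total, ratio`; `context` is `CG`
or `CH` (any non-CpG cytosine context), determined from the reference,
never from the read.

## Synthetic methylome model

**Genome.**  The background sequence is uniform random A/C/G/T with every
background CG dinucleotide erased, so CpG dyads exist only where the
generator plants them.  This makes the realised CpG landscape follow the
density plan exactly (up to Bernoulli sampling) and gives the density
recovery tests a sharp target.  Dyads are planted per bp at rate
`cpg_per_kb / 1000 × multiplier`; the multiplier is 0.5 inside PMD-like
domains (CpG-poor heterochromatin), 4 inside DPD-like domains (CpG-dense
active chromatin) and 8 inside CpG islands, which are placed over a
configurable fraction (default 0.5) of promoters.

**Domain architecture.**  Domains are megabase-scale intervals labelled
PMD-like, DPD-like or neutral.  The default plan tiles 500-kb slots with
PMDs covering ~25% and DPDs ~12.5% of the genome, spread evenly so even
short test chromosomes see both types.  Genes (fixed structure:
5′-UTR, exons and introns, 3′-UTR; promoter = 1 kb upstream, not part of
the gene) are never placed inside PMDs — these are gene-poor in real
genomes — and are steered into DPDs with probability `frac_in_dpd`
(default 0.5).  Repeat families (dispersed copies; satellite as one tandem
block) are placed outside planted domains so that per-domain methylation
deltas are not confounded by repeat-specific methylation.

**Truth methylome.**  Each CpG draws a true methylation probability from a
three-component Beta mixture: spikes near 0 and 1 plus a broad
intermediate component,

    p ~ w₁·Beta(0.5, 500) + w₂·Beta(5, 5) + w₃·Beta(500, 0.5)

with default weights (0.17, 0.35, 0.48) reproducing a bimodal normal-
tissue composition.  Both strands of a dyad share one probability.  The
spike components are deliberately sharp (means 0.001 / 0.999): with
read-level binomial sampling at ~7.5× per strand, a site whose true
probability were, say, 0.98 would show a discordant base in a substantial
fraction of piles and the planted state would not be recoverable at the
0.05/0.95 classification thresholds.  The spikes keep the planted state
identifiable while remaining biologically sensible (fully methylated
loci are maintained at near-unit probability).  Inside PMD/DPD-like
domains the baseline mixture is (0.02, 0.08, 0.90) — these domains are
almost fully methylated in normal tissue, which is what makes their loss
visible.  Condition effects are additive shifts applied inside domains
(PMD-like: −0.3 in both tumor conditions; DPD-like: −0.3 in the knockout
only), clipped to [0, 1] with clip counts logged.  Clipping matters where
unmethylated CpG islands sit inside a shifted domain: the realised
per-domain mean delta is attenuated from the nominal shift by the
fraction of near-zero sites (e.g. ~0.22–0.29 instead of 0.30 in
gene-containing DPDs); gene-free domains realise the nominal shift within
±0.03.  Repeat families get per-condition Beta-distributed per-copy
methylation (concentration 50) driven by one shared uniform per copy, so
identical condition parameters give identical values.  Non-CpG cytosines
default to probability 0, consistent with using non-CpG positions for
conversion estimation.

**Reads.**  Single-end reads (mate simulation is declined: a mate adds no
methylation information at the counting stage), sampled uniformly per
chromosome, half original-top and half original-bottom.  At a reference C
(OT) the read shows T with probability `(1 − p) × conversion_rate`; OB
reads mirror this as G→A.  Uniform substitution errors at `error_rate`
(default 0.001) are applied on top; bisulfite over-conversion of
methylated C is folded into this error term rather than modelled
separately.  Base qualities follow a two-level profile — high (Q40)
interior, low (Q20) tail over the last 5 cycles — so the quality-trimming
rule has something to act on.  Reads carry a `ZS:Z:+/-` tag for the
protocol strand and are written as SAM (OT = flag 0, OB = flag 16, with
the quality profile reversed in reference orientation for flag-16
records).

**Default sequencing parameters.**  Coverage 10× (the study conditions
this package emulates span ~9–18×; the default sits at the low-middle of
that range), read length 105 bp, conversion rate 0.99 per condition
(0.989–0.991 across conditions in the pipeline defaults), error rate
0.001.  In the *recovery experiments* (conversion-rate, state-fraction and
domain recovery) reads are simulated at the 80-bp analysis length with
uniform qualities, so that "coverage c" is delivered in usable post-trim
bases; with 105-bp raw reads the same nominal coverage yields only ~76%
usable depth and correspondingly more low-depth misclassification.  Both
readings of "coverage" are defensible; the usable-coverage convention is
used consistently and stated here.

**External tracks and expression.**  The lamina-association, H3K4me1 and
normal-expression tracks are built directly from the domain plan (20-kb
bins, domain indicator plus Gaussian noise, σ = 0.25): lamina high in
PMDs; H3K4me1 and expression high in DPDs, lowest in PMDs.  They emulate
the *correlation structure* of the real tracks, not their assay-specific
signal distributions — a passing correlation test shows sign and strength
recovery under the planted geometry, not realism of the signal model.
The expression table gives genes inside DPDs a >2-fold change (random
direction) with probability 0.9 and all other genes a null log₂ fold
N(0, 0.2).

## Calling

Trimming first truncates to 80 bp from the sequencing 5′ end (for a
reverse-strand alignment that end is the right end of the stored
sequence, so the alignment start shifts), then strips maximal terminal
runs with quality < 30 from both ends; a flag restricts stripping to the
sequencing 3′ end.  Reads emptied by trimming are discarded and counted.

Counting is a strand-independent pileup over reference cytosines: C calls
count as methylated, T as unmethylated, all other base calls are ignored;
sites with no informative calls are omitted.  SAM flags stand in for the
upstream mapping filters (unmapped, secondary, supplementary and
duplicate records are skipped).  Gapped alignments are accumulated per
gapless CIGAR block (deletions and reference skips inform nothing);
trimming is applied only to single-block alignments — gapped reads are
counted untrimmed, a simplification that is exact for all data this
package generates.  Protocol strand comes from the `ZS` (or Bismark-style
`XG`) tag, falling back to the alignment strand for untagged directional
libraries.

The conversion rate pools all non-CpG cytosine contexts (no CHG/CHH
distinction), strand-aware on both strands, with *all* base calls at
those positions in the denominator, and C calls in the numerator,
subtracted from 1.  With the simulator's error model the estimator has a
small known bias (≈ +e/3 false C calls), well inside the ±0.005 recovery
band at the default error rate.

A `pool_strands` option sums dyad counts for downstream convenience; all
analyses here keep strands separate.

## Composition and features

State thresholds: unmethylated < 0.05, fully methylated > 0.95, the
boundary values themselves classify as partial (the outer classes are
defined by strict inequalities).  Genome-wide distributions use every
covered site (coverage ≥ 1); promoter analyses require coverage ≥ 3 and
≥ 3 CpGs (CpG-island promoters > 5 CpGs).  Feature averages are
per-feature means of per-site ratios, strands pooled per feature, and the
category average is unweighted over qualifying features.  The genic
partition paints per-bp labels in ascending priority intergenic < intron
< 3′-UTR < 5′-UTR < exon < promoter, so overlapping records resolve
deterministically and every CpG is counted exactly once; partition
averages are site-level means within each label.  The − strand promoter
is the 1 kb downstream of the gene interval on reference coordinates.

## Windows and domains

Windows are a fixed non-overlapping tiling (stride = width); the trailing
partial window is kept in tracks but excluded from genome-wide flagged
counts by default.  The window value is the arithmetic mean of per-site
ratios (a pooled-counts mode exists behind a flag).  A window with zero
covered CpGs is missing, not zero, and never comparable.  Differential
flagging requires both windows defined; the flagged count equals the
number of flags exactly, and is non-increasing in the cutoff δ.
Merging flagged windows into domains uses gap tolerance 0 windows and
minimum run length 1 window by default (both configurable) — the mapping
from flagged windows to reported domains is an artifact decision, since
window thresholding alone does not define domain boundaries.  Conserved
PMDs require a window to be flagged in every replicate comparison;
with a single comparison the caller warns and degrades to
single-comparison domains.  External bedGraphs are resampled onto the
tiling by coverage-weighted means, gaps treated as missing.  Spearman
correlation requires ≥ 10 comparable windows and rejects constant inputs.

A rank-arithmetic note: with a near-binary loss signal over a fraction f
of windows, the attainable Spearman ρ against a matching binary track is
bounded by the between-group share of rank variance (≈ 0.47 at f = 0.2,
≈ 0.7 at f = 0.4).  High track correlations therefore require domain
architectures covering a realistic fraction of the genome — the
correlation validation uses PMDs over 40% of a 10-Mb genome, in line
with reports that hypomethylated blocks cover on the order of half of
tumor genomes.

## Expression association

Deregulated-gene selection is strict: up means fold > 2, down means
fold < 0.5; non-positive fold changes are rejected and counted.
Gene-to-window assignment defaults to the window containing the gene
midpoint (a span-weighted any-overlap mode exists).  The subregion test
is an unpaired Welch t-test (the two genotypes are distinct tumor pools;
a paired flag exists) per gene set × subregion at α = 0.01, skipping
cells with fewer than two genes per side.  Swapping the conditions flips
every t statistic and preserves p-values.  No methylation floor is
applied when selecting subregions for testing; users comparing against
analyses that restrict to highly methylated subregions should filter
`gene_subregion_means` output first.

Monte-Carlo calibration of this test simulates per-gene subregion means
directly (Normal around 0.7, between-gene SD 0.1, clipped to [0, 1],
independent per condition; planted effects as additive shifts on the
knockout).  Under the null the pooled rejection rate over 8 cells ×
1000 replicates falls inside the binomial 95% interval around 0.01, and a
planted −0.2 shift in one cell is detected in ≥ 95% of replicates while
every other cell stays inside its per-cell null band.  Note that
"every null cell non-significant simultaneously" is not a reachable
criterion at α = 0.01: with 7 null cells the joint probability is
0.99⁷ ≈ 0.93 for a perfectly calibrated test, which is what the
selectivity check above accounts for.

## Pipeline and determinism

The pipeline runs simulate → call → stats → domains → correlate →
expression for the three comparisons (tumor vs normal, knockout vs
normal, knockout vs wildtype), simulating a second wildtype-tumor read
replicate from the same truth for conserved-PMD calling.  All randomness
derives from one seed through per-purpose `SeedSequence` streams (the
condition name enters via a CRC so streams are stable across runs and
platforms).  Outputs are byte-identical across reruns with the same
config; the manifest records parameters, seed and SHA-256 checksums of
every file and deliberately contains no timestamps.  Stage toggles allow
re-running a stage from the files of an earlier run.

## Problem sizes

The validation suite works at desk scale, chosen so the full suite runs
in minutes: oracle-parity fixtures ≤ 10,000 reads; conversion recovery on
a 200-kb genome × 100 replicates per rate; state-fraction recovery on
~50,000 CpGs at 15×; domain recovery on a 10-Mb chromosome with
3 × 500-kb planted domains at 10×; correlation recovery on a 10-Mb genome
with 40%/20% PMD/DPD coverage; the determinism check on a 20-Mb
two-chromosome genome, full pipeline run twice.  These sizes are the
package's own validation conditions; the statistical structure (not the
absolute genome size) is what the checks exercise.

## Known limitations

- No PCR-duplicate, indel, M-bias or quality-dependent error modelling;
  base qualities are a two-level profile only.
- Non-CpG methylation defaults to zero; the conversion estimator assumes
  it (as does the field's standard estimator).  Simulating substantial
  non-CpG methylation biases the estimated conversion rate down —
  that interaction is a feature of the estimator, not of this
  implementation.
- Repeat analysis is per-genomic-copy (as for uniquely mapped reads);
  no consensus-sequence remapping.
- Domain calling is window thresholding with run merging, faithful to
  the emulated analysis; it is not an HMM/changepoint segmentation and
  will quantise domain boundaries to the window grid.
- The synthetic genome has uniform base composition and dispersed,
  non-nested repeats; passing tests demonstrate correctness of the
  analysis chain under the planted model, not performance on the
  compositional quirks of real genomes.
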