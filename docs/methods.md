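# Methods

`methmark` analyses the relationship between DNA methylation patterns,
histone modifications and sequence context in a genomic-region-aware way.
This note documents the models, the parameter choices that matter, and what
the synthetic benchmark does and does not demonstrate.

## Pattern calling

Per-CpG input is a table of (chromosome, position, methylated reads, total
reads), as produced by bisulfite aligners in the Bismark coverage
convention.  A region is a maximal run of at least `min_cpg` (default 4)
consecutive CpGs whose levels all qualify for one state — level ≤ `u_max`
(default 0.25) for unmethylated (U), level ≥ `m_min` (default 0.75) for
methylated (M) — with no inter-CpG gap above `max_gap` (default 500 bp) and
per-CpG coverage of at least `min_coverage` reads (default 4; zero-coverage
CpGs are always dropped because they have no level).  Partially methylated
CpGs break runs and never join a region.  The caller is a transparent
deterministic stand-in for published hotspot-extension segmentation tools:
its output is fully determined by four explicit thresholds, which makes it
testable against a brute-force linear scan.  The coverage floor of 4 reads
stabilises the per-CpG level estimate at the simulated mean coverage of 15;
at very low coverage a single read would otherwise flip a CpG between
states.

The region interval spans the first to the last CpG of the run (half-open,
end = last position + 1).  Raising `m_min` (or lowering `u_max`) can only
shrink the set of qualifying CpGs, so called region counts are monotone in
the thresholds — this is exercised as a property test.

## Genome partition

Gene-anchored windows, 0-based half-open, in transcription orientation:
promoter `[TSS−1000, TSS+500)`, gene body strictly between `TSS+500` and
`TTS−500`, downstream `[TTS−500, TTS+1000)`; intergenic is the complement.
Promoter and downstream windows are exactly 1,500 bp except where clipped
at chromosome edges.  The single base at `TSS+500` is excluded from both
promoter and gene body by the strict inequalities and falls to intergenic;
it is a measure-zero artefact of the window definition and never hosts a
region midpoint in practice.  Overlapping windows of different genes are
resolved by the precedence promoter > gene body > downstream (promoters are
the most conserved, headline category); multiple transcripts of one gene
are merged by union per category before the complement is taken.

Whole regions (patterns, DMRs) are assigned to the category of their
midpoint base, `floor((start+end)/2)`.  CpG-island membership is an
independent midpoint overlay, not a fifth partition cell.  Midpoint
assignment is a deliberate design choice: spanning regions could straddle
two categories, and centre-based assignment handles them uniformly and
deterministically.

## Sequence and mark features

For a region of length `L` with `N_C` cytosines, `N_G` guanines and
`N_CpG` CpG dinucleotides (plus strand):

* GC content = `(N_C + N_G) / L`
* CpG O/E = `(N_CpG · L) / (N_C · N_G)`, defined as 0 when `N_C·N_G = 0`

Histone-mark signal is pseudocounted RPKM: with `Reads` read starts in the
region and `N` total mapped reads for the mark,
`RPKM = (Reads + p) · 10^9 / (N · Length)`.  The default pseudocount
`p = N/10^9` puts the zero-read floor at exactly `1/Length` independent of
library size, keeps RPKM strictly positive (so fold changes are always
defined) and is configurable (`fixed:<c>` supported).  A read is counted in
a region iff its start coordinate lies inside it, which prevents double
counting across adjacent regions.  Signals are compared between conditions
as `log2(RPKM_2 / RPKM_1)`.

Signature clustering of (pattern × category × cell) mean profiles uses
average-linkage agglomerative clustering under Euclidean distance on
log2-RPKM rows; metric and linkage are package choices, fixed for
determinism.

## Classification protocol

U-vs-M prediction uses a random forest (Gini impurity splits, 500 trees by
default, `sqrt` features per split; any scikit-learn-style classifier can
be plugged in).  The protocol per evaluation: 10 sampling repeats; each
repeat draws a fresh class-balanced sample (majority class downsampled
without replacement to the minority size), runs stratified 10-fold CV, and
computes AUC from the pooled out-of-fold class probabilities of that
repeat; ACC, sensitivity and specificity are taken at probability 0.5.
Reported metrics are arithmetic means over repeats.  Pooling within a
repeat (rather than averaging per-fold AUCs) is stable at small fold sizes.
Feature-set comparisons (SF, HM, HM+SF) and cumulative top-n curves share
the sampling seeds so differences reflect features only.

Feature importance is mean decrease Gini: the forest's total
impurity-decrease attribution per feature (scikit-learn
`feature_importances_`, which normalises the sum to 1 — a monotone
transformation that leaves ranks unchanged), averaged over the sampling
repeats to stabilise the ranking.  The essential feature set is the top-6
by this ranking, with the cumulative curve's AUC at n=6 attached.

## DMR analysis

DMRs between two cell types are intersections of overlapping
opposite-pattern regions, typed U→M or M→U in the cell1→cell2 direction.
Every opposite-pattern overlap is emitted by default (`min_frac = 0`):
both cells have independently made confident per-CpG calls over the shared
bases, so the overlap itself is the evidence.  A reciprocal-overlap filter
(`min_frac` of the shorter region) is available but discouraged: because
each cell merges a flipped segment with *different* same-state neighbours,
the genuine intersection is routinely a small fraction of the shorter
merged region, and a 0.5 cut silently discards ~15% of true
single-segment flips while (measured on the planted benchmark) removing no
false calls at all.

Informative effectors per genomic category are marks whose per-DMR log2
fold changes differ between U→M and M→U by a two-sided Wilcoxon rank-sum
test at raw p < 0.001 — an uncorrected cut by design, with an optional
Benjamini–Hochberg flag.  The test is exact when both groups have ≤ 20
observations and no ties, and otherwise uses the tie-corrected normal
approximation without continuity correction: at 30-vs-30 the empirical
type-I rate at α = 0.001 is 0.0010 without the correction (0.0009 with),
so the uncorrected statistic tracks the nominal level.  Two-sided testing
is the safe choice since effects in both directions are of interest.
Effector candidates default to the union of the two cells' essential
histone marks; `all` marks is a configuration switch.  Class prediction
then applies the balanced CV protocol to the effectors' fold changes with
U→M as the positive class.

## Co-variation and enrichment

Co-var1 is the set of U→M DMRs whose H3K4me2 and H3K4me3 fold changes are
both strictly below their class-wise 0.75 quantile; Co-var2 the M→U DMRs
with both strictly above their class-wise 0.25 quantile (linear
interpolation between order statistics).  The literal < Q3 / > Q1 reading
is the default; a `strict` switch tightens to < Q1 / > Q3 for users who
prefer selecting the strongest quarter.  DMRs map to genes through the
gene-region window containing the DMR midpoint, per region class (PG/GG/DG
for promoter / gene body / downstream), deduplicated.

Gene-set enrichment is a one-sided hypergeometric tail `P(X ≥ k)` against
a user-supplied background and GMT-style annotation sets, BH-adjusted
across sets.  Region-overlap enrichment treats a universe of regions as
the population, those overlapping the target as successes and those
overlapping the query as draws, reporting the overlap fraction `k/K` and
the same one-sided tail.

## Synthetic benchmark

The generator emulates the statistical structure the analysis assumes —
nothing more.  A genome (random sequence, GC ≈ 0.40) is tiled into
geometric-length segments (mean 2,000 bp) that alternate U/M states; CpG
sites are the genuine CG dinucleotides of the sequence, thinned to ~1 per
50 bp outside CpG islands and kept dense (~1 per 8–10 bp) inside islands,
which are planted as GC- and CpG-enriched subsequences (GC ≥ 0.5,
O/E ≥ 0.6 by construction) and biased toward the U state
(`island_u_bias = 0.85` vs `u_fraction = 0.4` elsewhere) — the mechanism
that makes sequence features partially informative, as in real genomes.
Per-CpG counts are beta-binomial: coverage ~ Poisson(15), level ~
Beta(8, 2) in M segments and Beta(2, 8) in U segments, independently per
cell.  Cell 2 shares the genome and annotation and flips the state of a
configurable fraction of segments (default 0.1), which defines the
ground-truth DMRs.  Mark reads are 36 bp intervals placed uniformly per
segment with Poisson counts at density
`background · 2^(±effect_size/2)`, the sign set by the mark's direction
(active marks prefer U, repressive prefer M) and the segment's state in
that cell.  Genes are separated by ≥ 3 kb so adjacent promoter/downstream
windows cannot collide.

Two generator defaults were calibrated, once, to make the planted regimes
meaningful and are then left alone:

* `background_density = 15 reads/kb`.  Called regions fragment to a median
  of a few hundred bp under Beta(8, 2) noise at coverage 15, so a region
  carries `density × length` reads; 15/kb gives roughly 4–8 background
  reads per region — within the range of local read densities of real
  ChIP-seq compendia — which is enough for an effect-size-2 mark (4× density
  ratio) to be resolved.  At this depth three active marks at effect size 2
  yield mean AUC ≈ 0.98 and a fully null panel sits at chance.
* The 16-mark default panel mixes strongly informative active marks
  (H3K4me2/me3, H3K9ac at effect 2), weaker active marks, repressive marks
  (H3K9me3 at 1.5, H3K27me3/H3K36me3 at 1) and eight null acetylation
  tracks, mimicking the redundancy of real compendia; consequently the
  top-6 essential features predict within ~0.01 AUC of the full 18-feature
  model.

What the synthetic data does **not** model: realistic sequence composition
(beyond island structure), read-level error, replicate structure,
fragment-size effects, input normalisation, partially methylated domains,
or any coupling between gene positions and methylation state.  Passing
benchmarks therefore demonstrates that the machinery recovers planted
structure of the assumed form at realistic signal-to-noise — not that the
biological conclusions transfer to any particular real dataset.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng`; generator
  stages use independent child streams, and the pipeline derives per-stage
  seeds from the master seed by CRC32 of the stage name (mod 2^31), so no
  two stages share a stream and a fixed master seed makes the whole output
  bundle byte-identical across runs.
* The chi-square test of pattern-by-category association uses no
  continuity correction, matching the textbook statistic on 2×2 tables; a
  degenerate (single-row/column) table reports statistic 0, p 1.
* Pearson correlations with a zero-variance side are reported as
  not-available (NaN with a `defined` flag), never as 0.
* Importance ties are broken by feature configuration order, making ranks
  a deterministic permutation.
* Benchmarks in the test suite and the acceptance script run at reduced
  problem sizes — genomes of 0.25–20 Mb, forests of 40–150 trees, 2–5
  sampling repeats — chosen so each planted effect is resolved with margin
  while the whole suite stays fast; the library defaults (500 trees, 10
  repeats) are what an analysis of real data would use.

## Known limitations

* The pattern caller is a simplified stand-in; counts from
  hotspot-extension segmentation tools on real data will differ, so
  region/DMR totals are not comparable with published tallies.
* The exact published pseudocount expression is not recoverable; the
  `N/10^9` floor is one defensible choice and numbers that depend on it
  cannot be matched bit-for-bit against prior work.
* Midpoint category assignment is a package convention for regions that
  straddle category boundaries.
* The hypergeometric gene-set enrichment replaces curated annotation
  services; biological term content depends entirely on the GMT files the
  user supplies.
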