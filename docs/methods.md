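# Methods

This note records the statistical model behind each pipeline stage, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the numerical conventions adopted where the underlying
analysis tradition leaves details open.

## Experimental design assumed

All expression operations assume the canonical panicle heat-shock layout:
six conditions — untreated control (CK) and 20 min, 60 min, 2 h, 4 h, 8 h
of 40 °C treatment — with two biological replicates each, measured on
single-channel arrays (12 samples). The design table is explicit in every
dataset, so other replicate counts work, but the detection-flag threshold
and several defaults are tuned to this 12-sample shape.

## Normalization and QC

Values are log2 intensities throughout. Quantile normalization replaces
each within-column rank by the cross-sample mean of the values at that
rank; ties within a column receive the mean of their tied rank-means. The
defining property — identical sorted value vectors in every column — holds
exactly for tie-free (continuous) data; with ties the tie-averaging rule
takes precedence, so tied columns can deviate from the shared distribution
by the averaged amount. Baseline-to-median subtracts each probe's
across-sample median (idempotent; median of a centered row is 0).

Replicate QC computes all pairwise Pearson correlations and a
complete-linkage tree on 1 − r. The QC bar for replicate pairs defaults to
r ≥ 0.99, the conventional standard for well-behaved array replicates; a
zero-variance sample has undefined correlation and fails its pairs
outright.

## Filtering and fold-change calls

- **Flag filter**: keep probes with a P (present) call in at least 6 of 12
  samples; for other sample counts the threshold rescales to
  ceil(n/2) with a warning. Missing flags are treated as A (absent) —
  the conservative reading.
- **Fold changes** are differences of replicate-mean log2 values
  (equivalently, log ratios of geometric means), not ratios of linear
  means — the standard convention once data are log2-transformed.
- **Differential** at time t: |log2FC| > log2(3), *strict* — "more than
  3-fold" excludes a probe sitting exactly at 3-fold.
- **Heat-responsive (HR)**: differential in ≥ 2 of the 5 treatment time
  points, direction-agnostic across time points (an early-induced,
  late-repressed probe qualifies; temporal reversal is a real expression
  class, not an artifact).
- The **all-time-point set** intersects differential status (either
  direction per time point) across all five time points, again without
  requiring a consistent direction.
- Gene-level sets use the *any-probe* rule: a gene is in a set iff at
  least one of its probes is. Gene counts therefore never exceed probe
  counts, and probes without annotation are dropped with a warning.

These are pure fold-change rules; with two replicates per condition a
variance-based test would be underpowered, and the fold-change tradition
keeps the calls transparent.

## Clustering and pattern labels

k-means uses Euclidean distance, k-means++ initialization and 10 seeded
restarts (best within-cluster sum of squares kept), making results
deterministic given a seed; scikit-learn provides the optimizer. The
default k = 12 matches the granularity at which this kind of time course
resolves into distinguishable temporal classes. Input space is a choice:
the 12 normalized sample columns or the 5-point log2FC trajectories; the
log2FC space removes per-probe baseline differences and is what the tests
and acceptance study use. Hierarchical clustering (complete linkage,
Euclidean or 1 − Pearson) supplies trees and heatmap leaf orders.

Pattern labels formalize what is usually done by eye. With an early
window (20 min, 60 min, 2 h), late window (4 h, 8 h) and threshold T = 1
(log2 units, i.e. 2-fold), precedence order: continuous-up (all five
points ≥ T), continuous-down, early-down-late-up (early mean ≤ −T and late
mean ≥ T), early-up / late-up (one window mean ≥ T, the other below),
early-down / late-down (mirror), else mixed. Labels depend only on log2FC
versus CK, so they are invariant to array-wide intensity shifts. The
threshold is exposed (`up_thresh`).

Category over-representation per cluster uses the same hypergeometric
upper tail as the motif analysis, on raw p-values at α = 0.05 by default.
A Benjamini–Hochberg option exists but is off: with a handful of
categories per figure the tradition here reports raw p, and fidelity comes
first. The same applies to motif enrichment below.

## Hypergeometric statistics

For a cluster of M genes in a database of N, of which m and n carry a
property, enrichment is scored by the upper tail

p = Σ_{i=m}^{min(n,M)} C(n,i) C(N−n, M−i) / C(N, M),

computed from log-gamma terms with log-sum-exp, clamped to (0, 1] — a
planted signal of hundreds of genes produces p-values far below double
underflow if computed naively. The enrichment ratio is (m/M)/(n/N); a
motif absent from the whole database has no background frequency and is
skipped. The implementation is checked against exhaustive subset
enumeration for every population of size ≤ 12 (|Δp| < 1e-12) and against
an independent library tail function on larger random parameters.

## Promoter scanning and co-occurrence

Motifs are IUPAC consensus strings (minimum 4 bp) matched exactly under
the degenerate-code table, on both strands, at every offset, overlapping
matches included; deterministic consensus matching suits PlantCARE-style
elements and keeps every count reproducible, whereas PWM scanning is out
of scope. A consensus N matches any base; an N *in the sequence* (masked
base) matches nothing. Coordinates are 1-based within the promoter string,
5′ to 3′; a reverse-strand match is reported at the forward coordinate of
its leftmost base; a strand-palindromic consensus yields one occurrence
per position. The −3000..−1 genomic span is metadata: truncated promoters
simply give shorter strings.

Counting is per gene: n(motif) counts genes with ≥ 1 match. Two distinct
motifs co-occur in a gene when some pair of matches lies within the window
(default 250 bp), measured start-to-start (|Δstart|, strand ignored); an
edge-to-edge `gap` mode is available since the anchor convention is a
genuine choice. Co-occurrence is recorded at most once per promoter
regardless of multiplicity, and self-pairs are excluded. Pair significance
uses the hypergeometric tail with t/T (cluster) and k/K (database) counts
of genes carrying the windowed pair.

Significance classes use strict upper bounds, assigning boundary values to
the less significant class: nodes diamond (p < 0.001), triangle
(0.001 ≤ p < 0.05), circle (p ≥ 0.05); edges solid (p < 0.01), dash
(0.01 ≤ p < 0.05), absent otherwise. The network export carries node
size = cluster carrier count m, node color = enrichment ratio, node
shape = class, and only p < 0.05 edges, as SIF + attribute tables or
GraphML.

## qPCR quantification

2^(−ΔΔCT) with technical replicates averaged on the CT scale (standard
practice; averaging on the RQ scale differs only at second order in the
CT spread), ΔCT = CT_target − CT_reference within each condition and
biological replicate, ΔΔCT against the calibrator condition (CK) within
the same biological replicate, and RQ averaged across biological
replicates with its SD. The calibrator's RQ is exactly 1 by construction,
and RQ is invariant to condition-wide CT shifts (reference and targets
moving together). Concordance with the array reports the fraction of
(gene, time point) observations where sign(log2 RQ) = sign(log2FC) and
the Pearson r of the two vectors. Amplification-efficiency correction
(Pfaffl) is out of scope.

## Synthetic data: what it emulates, and what not

**Expression.** Per-probe baseline ~ N(8, 2.5²) log2 units, planted
additive log2FC profiles at the treatment time points, i.i.d. Gaussian
noise (default SD 0.25 — typical log2 replicate scatter for arrays; at
these settings replicate correlations land just above the 0.99 QC bar),
and independent per-cell absent calls at rate 0.3 (about 62% of cells P,
so ~96% of probes survive the 6-of-12 filter). The twelve default profile
archetypes span early/late/continuous regulation in both directions plus
the early-down-late-up reversal, with magnitude variants of the abundant
early-up and late-up classes; 60 planted probes per archetype in 5,000 is
the standard study. Linear intensities are never materialized. Not
emulated: probe-level sequence effects, dye/batch structure,
intensity-dependent variance, correlated noise — so passing tests show
algorithmic correctness, not robustness to array artifacts.

**Promoters.** I.i.d. background sequence at configurable GC content
(default 0.45, in the range of rice upstream regions); no dinucleotide or
positional structure. The motif library names evoke the stress-responsive
elements central to heat-response promoter work (HSE, ABRE, CE3, GCC box,
GC repeat, Box I, W box, MYB site) but the consensi are synthetic 10-14-bp
stand-ins: the natural cores (e.g. GCCGCC) are so short that chance
matches would saturate a 3-kb i.i.d. background (~1.5 expected hits per
promoter), leaving no background frequency to enrich against. Longer
consensi keep chance carriers rare so planted frequencies are
interpretable. Planted sites never overlap (redrawn on collision); pair
plants place the first motif uniformly at random and the second exactly
`distance` bp downstream, start-to-start — matching the co-occurrence
distance convention. Cluster genes receive unplanted motifs at background
frequency, so an unplanted cluster is exchangeable with the background —
the property the null calibration relies on. The standard planted study:
200 background + 40 cluster genes, every motif at 10% background, one
motif at 80% in the cluster, one pair at distance 100 in 60% of cluster
genes versus 2% of background.

**Null calibration.** 100 simulations of 500 background + 100 "cluster"
genes (1-kb promoters — gene-level carrier frequencies do not depend on
length since carriers are planted, and shorter sequence keeps the study
fast), 8 motifs at background frequencies 0.15-0.50. The spread of
frequencies matters: the hypergeometric tail is discrete, so the largest
attainable p below 0.05 sits somewhat under it and the test is
conservative; with carrier counts in the hundreds the granularity is fine
enough that the pooled false-positive rate stays within 3 binomial
standard errors of the nominal 0.05 (observed ≈ 0.04).

**qPCR.** Reference gene fixed at CT 18, targets at base CT 24 minus the
true log2FC, i.i.d. Gaussian CT noise per well (default studies use SD
0.1, a typical SYBR technical spread), 2 biological × 3 technical
replicates. Not emulated: efficiency differences between primer pairs,
pipetting covariance, plate effects.

## Problem sizes and determinism

The acceptance study uses 5,000 probes for the expression stage, 240 genes
for the planted promoter stage, 100 null simulations (800 pooled tests)
for calibration and a 10-gene plate for qPCR — sizes at which every
planted effect is comfortably detectable while the full run stays around a
minute on one CPU. All randomness flows from numpy `default_rng` seeded
from a single `--seed`; sub-studies draw child seeds below 2^31 from the
root generator. k-means restarts, hierarchical ties and flag draws are all
deterministic given the seed.

## Known limitations

- Fold-change-only differential calls have no error model; near-threshold
  probes flip with noise (visible as <100% recovery at realistic noise).
- Raw p-values by design; with many motifs or categories the user should
  enable the BH option.
- Consensus scanning cannot grade match quality; degenerate positions
  count as full matches.
- The co-occurrence window anchor (start-to-start vs gap) changes counts
  for long motifs; both modes are exposed but defaults follow the
  start-to-start convention.
- The generators' independence assumptions (i.i.d. noise, independent
  flags, i.i.d. sequence) make recovery easier than on real arrays and
  genomes; results on synthetic data bound what the algorithms can do,
  not what a given real dataset will yield.
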