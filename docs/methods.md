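# Methods

This note records the statistical models implemented in `lcmarray`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter when
reproducing results.

## Study designs

Two fully crossed designs are modeled. The GF/CR comparison crosses
2 tissues (ileum, colon) × 2 epithelial fractions (tip, crypt) ×
2 bacterial statuses (germ-free, conventionally raised) with 5 biological
replicates per group — 40 arrays. The colonization course replaces status
by day ∈ {0, 1, 3, 5, 7} with 3 replicates per group — 60 arrays, 100 in
total. Sample identifiers encode the factors
(`<tissue>_<fraction>_<condition>_r<k>`), and every analysis that splits
by fraction operates on the 10 (or 15) samples of one tissue × fraction
block.

## Normalization

Quantile normalization equalizes the per-sample value distributions: the
target is the across-sample mean of order statistics, and a run of tied
values within a sample receives the mean of its tied targets, making the
map rank-based and exactly idempotent. The input is assumed to be a
summarized probe-set × sample matrix on the log2 scale; a heuristic
(`log2_if_needed`, threshold 50) transforms linear-scale input and records
the decision in the matrix provenance. Probe-level background correction
and summarization are out of scope.

## Moderated t contrasts and specificity

Each fraction's CR−GF contrast uses a two-sample moderated t. The
residual variance is pooled within the contrast (d_g = n_CR + n_GF − 2 =
8), not taken from a global linear model, because fractions are analyzed
separately throughout. The prior (d₀, s²₀) is fitted per contrast by
moment matching of log s²_g: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess of Var(e) over
ψ′(d_g/2) identifies d₀ through the trigamma inverse, and the mean of e
then gives s²₀. When no excess dispersion remains, d₀ = ∞ and s²₀ is the
mean observed variance; the statistic then reduces to a z-like statistic
with the prior variance, while d₀ → 0 recovers the ordinary pooled t
(both limits are asserted numerically in the tests).

Benjamini–Hochberg adjustment is applied per contrast and the
significance gate is **adjusted** p < 0.001. The four per-fraction
significant sets are partitioned into all 2⁴ − 1 Venn regions; the
specificity summary reports the sum of the exclusive regions over the
union, with the percentage rounded to the nearest integer. Degenerate
genes (zero variance and zero difference) are assigned t = 0, p = 1.

## Time-course gating and consensus clustering

Per fraction, genes are gated by a classical one-way fixed-effects ANOVA
across day groups, BH-adjusted, at adjusted p < 0.001. Gated genes are
summarized as per-day replicate means and z-scored across days so that
trajectory *shape*, not expression level, drives clustering.

Consensus clustering then repeats, for each K in 2..6 (default): subsample
80% of genes without replacement, cluster the subsample into K groups by
average-linkage hierarchical clustering on Pearson correlation distance
(d = 1 − r; k-means available behind a flag), and accumulate co-clustering
counts. consensus(i, j) is the co-clustered count over the co-sampled
count. Defaults of 250 resamples, 80% subsampling and K ∈ 2..6 are
conventional desk-scale settings.

K is selected by a plateau rule on the area under the consensus CDF: the
cut level K* is the largest K whose relative area increase is ≥ 0.1.
Because a single aberrant gene can form a perfectly stable singleton —
inflating the apparent cluster count — clusters in the K* cut smaller
than 3 genes are treated as outliers: the reported `chosen_k` counts only
substantive clusters, and outlier genes are reassigned to the substantive
cluster with which they co-cluster most often. The final assignment cuts
an average-linkage tree of (1 − consensus) at K*. Per-cluster trajectories
report mean ± sd (across member genes) of the replicate-averaged day
values, with member counts.

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k) for overlap k between an n-gene list and a K-member term in an
N-gene universe; the universe is the set of genes on the normalized
matrix. For GO-style collections, p-values are BH-adjusted across terms
and a term passes at adjusted p < 10⁻⁵ with more than 5 overlap members
(members counted within the universe). For regulator/miRNA target maps,
the observed Fisher p is compared with an empirical background: the mean
Fisher p over 1,000 uniformly drawn gene lists of the same size. A
regulator is called enriched when its Fisher p is below both the
background mean and a significance ceiling (0.05 by default) — the
background construction is prescribed, the decision rule is this
package's operationalization. The 50 most significant regulators per
fraction (ties broken by larger overlap, then identifier) are merged into
a unique list; sharing across all four fractions and exclusivity to one
are reported as rounded percentages. Enrichment is intended to be run
separately on up- and down-regulated lists so direction can be labeled.
The hypergeometric test stands in for a full gene-set-statistic framework;
only over-representation (not depletion) is tested.

## Promoter scanning

Motifs are per-position base-probability matrices (rows sum to 1, length
≥ 4). A pseudocount of 0.01 is added per cell before renormalization so
log-odds scores stay finite; scores are in bits against a background
distribution (uniform by default), with N bases contributing 0. Both
strands are scanned; a gene is a target when some window reaches a
caller-set fraction (default 0.8) of the motif's maximum attainable
score. Coordinates are 0-based half-open on the forward promoter
sequence; a reverse-strand hit at reverse-complement position p maps to
forward start L − p − w. The false-positive rate on random background is
not bounded by construction — it depends on motif information content —
and should be inspected per motif.

## qPCR quantification

ΔCt = Ct_target − Ct_reference per sample (reference L32); ΔΔCt subtracts
the mean ΔCt of the calibrator group, GF within the same tissue and
fraction by default (the calibrator is a flag); relative expression is
2^(−ΔΔCt), i.e. amplification efficiency is fixed at 2. "nd" wells are
treated as missing and dropped with a logged count; a missing reference
well is an error naming the sample. Significance testing uses a two-way
fixed-effects ANOVA (status × fraction with interaction, Type-II sums of
squares for mild imbalance) on the ΔCt scale by default — testing on the
log scale is the safer default since fold changes are log-normal; a flag
can switch the response.

## Synthetic data: what it emulates, and what it does not

Baseline log2 intensities are N(7, 2) — a typical microarray dynamic
range. Regulated genes get an additive CR effect whose magnitude is
Gamma-distributed around `effect_size_mean` (default 2 log2 units, shape
16 so effects concentrate near the mean) with random sign; 8.6% of genes
are regulated in exactly one tissue × fraction and 1.4% in all four, so
~10% of the transcriptome is regulated and 86% of regulated genes are
fraction-specific by construction. Residual noise is N(0, 0.35²) per
array by default, with an optional inverse-chi-square per-gene variance
model (`variance_prior_df`). Per-gene baseline signatures for the
non-reference fraction (sd 2) and tissue (sd 1) dominate the status
effects, so sample-level clustering separates fraction first, then
tissue, then status.

Time-course archetypes: strong responders (archetypes 1/2) step by ±2
log2 units after day 3 in the ileum and after day 1 in the colon (the
faster colonic response); mild responders (3/4) change by ±0.75 log2
units as a gradual ramp over the whole period. The ramps are deliberate:
clustering works on z-scored profiles under Pearson distance, both of
which are scale-invariant, so a "mild step" would be indistinguishable
from a strong step — archetypes must differ in shape to be four
recoverable clusters. Time-course arrays use residual sd 0.1: a power
analysis of the ANOVA gate (adjusted p < 0.001, 3 replicates/day) shows
mild ±0.75 trajectories need roughly F ≳ 30 (raw p ≈ 3·10⁻⁵) to survive
BH, which bounds the noise a recoverable mild archetype can carry.

Gene-set collections plant truly enriched terms per fraction by sampling
a proportion `enrichment_strength` (default 0.8) of each planted term's
members from that fraction's regulated genes; remaining terms are uniform
draws. Promoters are i.i.d. background (uniform A/C/G/T by default) with
motif consensus sites written at recorded positions and strands. qPCR
plates set Ct_target = Ct_ref + offset − log2(level) + noise so a true
fold change f yields E[ΔΔCt] = −log2(f) exactly.

The generator does **not** emulate: probe-level structure (PM/MM probes,
CEL files), correlated gene–gene noise, batch or array-lot effects,
realistic GO DAG structure, genomic promoter sequence composition, or
amplification-efficiency variation in qPCR. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
assumed noise model, not robustness to real-array artifacts.

A single pipeline seed fans out to per-module child streams via
digest-keyed spawn keys (process-independent), so each generator is
reproducible in isolation and end-to-end runs are byte-identical for a
fixed configuration and seed.

## Numerical conventions and degenerate inputs

* Trigamma inversion by Newton iteration (relative tolerance 1e-10) with
  asymptotic fallbacks at the extremes.
* Hypergeometric tails come from scipy's survival function; p-values are
  clipped into (0, 1].
* Pearson distances are symmetrized and clipped into [0, 2]; constant
  profiles are an error naming the offending item.
* BH is the exact step-up formula; monotonicity in the raw p-values is
  property-tested against a brute-force oracle.
* Ties in top-k regulator selection break by larger overlap then lexical
  identifier, so selection is invariant under record shuffling.
* TSV serialization writes floats with full `repr` precision and reads
  them back with round-trip parsing, making write→read bit-exact.

## Problem sizes used in tests and acceptance

The GF/CR recovery checks run at the full synthetic scale (20,000 genes ×
40 arrays). The colonization recovery runs at 4,000 genes × 60 arrays —
four per-fraction consensus clusterings of ~120 gated genes × 250
resamples each — which preserves the per-fraction planted structure while
keeping a complete run in seconds. Null-calibration checks use 10,000 to
20,000 null genes so the binomial tolerance around nominal error rates is
tight.

## Known limitations

* The linear model is strictly two-group per fraction; multi-factor
  contrasts, interactions and batch covariates are out of scope.
* `run_colonization` on user-supplied (non-simulated) matrices is not yet
  wired into the pipeline entry point; the `cluster-timecourse` command
  and the library functions handle real data directly.
* Regulator enrichment's empirical background assumes a uniform null over
  the universe; expression-matched backgrounds are not implemented.
* The motif scanner reports fraction-of-maximum thresholds, not
  p-value-calibrated ones, so hit counts are not comparable across motifs
  of different information content.
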