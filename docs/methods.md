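# Methods

This note documents the models, numerical choices, and open design
decisions behind `scmethrna`, and what the synthetic-data-based tests do
and do not establish about real data.

## Study design assumed

Two groups of single cells profiled in parallel for CpG methylation
(bisulfite sequencing at sparse, 0.5-3x-like coverage) and polyadenylated
transcript abundance (full-length scRNA-seq counts). Group 1 is the
treatment-like condition (in-vitro-matured, low-competence oocytes in the
motivating study), group 2 the reference (in vivo). All comparisons are
group 1 relative to group 2.

## Quality control

RNA gates (conjunctive; lower bounds inclusive, upper bounds inclusive):
reads >= 25 000, detected genes in [5 000, 7 500], total molecules
<= 2 000 000, mitochondrial percentage <= 5. The printed thresholds of
the underlying study are ambiguous about inequality direction; we adopt
the convention in which the stated numbers act as Seurat-style upper
bounds combined with explicit lower bounds — any other reading removes
essentially every cell. Bisulfite gates: >= 500 000 CpGs covered and
global CpG methylation strictly inside (30%, 70%); the boundary is
exclusive because values *at* 30%/70% fall outside the "between" reading.
Defaults describe full-genome data; for the synthetic genome the demo
config scales them (min CpGs 1 000, min reads 500, min genes 50). A
TSS-area methylation z-score (|z| > 3) is computed as a diagnostic only:
no operational exclusion rule exists for "altered TSS patterns", so it
never removes cells by default.

## Region-level methylation

All internal intervals are 0-based half-open; Bismark's 1-based positions
are converted only at the I/O boundary. CpG dyads can optionally be
collapsed (plus/minus-strand calls at p, p+1 summed), which roughly
doubles effective coverage at these depths. Region pooling is
read-weighted (sum counts then divide): at a handful of reads per CpG,
averaging per-CpG fractions gives each shallow CpG the same weight as a
deep one and is unstable; a `cpg_mean` option is provided for
sensitivity analysis. Only CpGs with >= 5 reads enter any region
estimate (rule 1 of the DMR cascade, applied at aggregation).

VMR detection is a transparent variance-rank surrogate for published
VMR callers whose internals are not described: windows covered in at
least half the cells are ranked by across-cell sample variance (ddof 1),
the top 2% are selected, and genomically adjacent selections are merged
into variable-length regions ranked by their maximum window variance.
Both the top fraction and the coverage floor are config.

## DMR calling

Rules 2 and 3 of the cascade: a region is kept iff, in each group,
at least ceil(0.5 x group size) cells have reads in it, and the mean
over contributing cells of the region's total qualifying read count is
strictly > 10. "Average reads of cytosines" is read as the per-region
read total averaged over cells; a per-CpG-coverage alternative
(`rule3_mode`) is provided since the original phrasing admits both.

The per-region test is a two-sample t-test on cell-level methylation
fractions. The default is Welch (unequal variances,
Welch-Satterthwaite df) because that is the default behavior of the R
`t.test` function named by the source protocol, even though the
protocol calls it a Student t-test; a pooled-variance `student` variant
is available. Significance requires p < .05 **and** an absolute group
difference > 0.1 — the "FC > 0.1 (10%)" threshold is interpreted as 10
percentage points of methylation, not a ratio, as the parenthetical
suggests. No multiple-testing correction is applied by default,
matching the raw-p protocol; BH is available behind a flag. Per-group
hyper (> 75%) / hypo (< 25%) labels use each group's own mean, so "42 of
52 labeled DMRs hypomethylated in group 1" counts group 1's own labels.
Regions where a group has fewer than two covered cells after the cascade
are reported as `untested`, never silently dropped. Degenerate
zero-variance comparisons return t = 0, p = 1 for equal means.

## Differential expression

A from-scratch NB engine, deliberately transparent rather than a clone
of any published package; its acceptance surface is calibration and
recovery, not byte-equivalence.

- Size factors: median of ratios to per-gene geometric means over genes
  expressed in every cell, normalized to geometric mean 1; library-size
  fallback (with warning) when no gene is ubiquitous.
- Dispersion: per-gene method of moments on normalized counts using the
  within-group pooled variance, clipped to [1e-8, 10], then shrunk
  (default weight 0.5) toward a binned-median mean-dispersion trend.
- Wald statistic: the log ratio of pseudocount-stabilized (pc = 0.5)
  normalized group means over a delta-method SE from Var(y) = mu +
  alpha mu^2. The statistic is referred to a t distribution with
  n1 + n2 - 2 df rather than a normal: at ~30 cells the normal
  reference is visibly anticonservative and the t reference keeps null
  p-values uniform (verified by KS in the test suite).
- Genes expressed in fewer than 3 cells are untested (p missing,
  excluded from the BH m).
- DEG thresholds: FDR < .05 and |log2FC| >= 2. A figure caption in the
  source reports +-1.5; the Methods-section threshold of 2 wins as the
  default and both are config.

HVG selection (variance of log1p-normalized counts standardized by a
binned-median mean-variance trend, deterministic id tie-break) feeds the
PCA embedding only; testing uses all genes passing the expression
filter. PCA uses SVD on centered/scaled HVG data with a deterministic
sign convention (largest-|loading| gene coordinate positive).

## Integration

The joint factorization replaces a published cell-aggregation NMF used
as a black box in the motivating study: we minimize
`||X_rna - W_r H||^2 + lambda ||X_meth - W_m H||^2` (lambda default 1)
by multiplicative updates, which guarantee a non-increasing objective;
determinism comes from seeded uniform initialization. With lambda = 0
the factorization uses expression only and W_m is fit post-hoc. Missing
methylation entries are imputed by the region's cross-cell mean before
factorization (NMF needs complete input); the correlation analysis
instead uses pairwise-complete observations and never imputes. Factor
markers use a Wilcoxon rank-sum test of assigned-vs-rest cells with a
natural-log fold-change > 0.25, the convention of the single-cell
toolkits this mirrors.

Methylation-expression correlation is computed within each group
(the motivating study reports per-group counts), over cis candidate
pairs: locus midpoint to annotated TSS < 500 kb on the same chromosome,
with >= 5 complete observations per group. The three reported
thresholds are applied as: |r_group| >= 0.5, |r_group - r_other| > 0.1,
and a guard requiring the pair's best |r| > 0.2 (redundant given the
first clause but retained as an independently switchable config gate,
since the source's three thresholds are not mutually unambiguous).

## Synthetic-data generator

The generator defines the study conditions for every test: 16 cells per
group; a latent methylation level per 1-kb window drawn Beta with mean
0.47 (the observed global level in mature oocytes) and concentration 6;
per-cell window fractions Beta-distributed with dispersion rho = 0.08,
shared by the CpGs of a window (cell-level, not CpG-level, noise — the
scale on which the region t-test operates); CpG sites at exponential
spacing (mean 80 bp), captured per cell with probability 0.3 and
covered by 1 + Poisson(9) reads, emulating post-dyad-collapse coverage
of sparse single-cell bisulfite data. Imprinted gDMRs are pinned near 0
or 1 identically in both groups, encoding the expectation that germline
imprints survive maturation conditions. Planted DMR windows shift the
latent level by +-0.4 in group 1, with the sign drawn among feasible
directions so the full effect is planted rather than clipped.

Expression: gene means log-normal(1.5, 1.2), library sizes log-normal
(sigma 0.25, geometric mean 1), counts Gamma-Poisson with dispersion
0.3, mitochondrial genes scaled to 2% of baseline output. Planted DEGs
multiply group 1 means by 2^(+-2.5) and are drawn from genes with
baseline mean >= max(10, median): with pseudocount 0.5 the log2FC
*estimand* for an effect on a gene with mean below ~5 cannot reach the
|log2FC| >= 2 calling threshold, so planting there would test the
pseudocount, not the caller.

Two stylized fixtures support the integration tests: block-structured
non-negative paired matrices (disjoint active features per group) for
factorization recovery, and paired promoter/expression matrices in which
planted pairs share a latent factor in group 1 only, giving strong
negative within-group-1 correlations.

What the generator does **not** emulate: fragment-level coverage
autocorrelation (CpGs are captured i.i.d.), bisulfite conversion
failure, doublets, batch effects, sequence-driven CpG density (CGIs are
placed, not compositionally defined), and any coupling between the
methylome and transcriptome outside the dedicated coupled fixture.
Passing tests therefore demonstrate the correctness and calibration of
the statistical machinery under the stated model, not robustness to
those real-data phenomena.

## Problem sizes

The test and acceptance runs use down-scaled genomes chosen so every
property is measured with adequate replication: null calibration on
~3 000 retained 1-kb windows (2 x 1.5 Mb) and ~2 000 genes (16 + 16
cells); recovery on 60 planted DMRs and 200 planted DEGs; coupling
recovery on 40 planted promoter-gene pairs over 28 cells; and a
2 x 300 kb end-to-end demo. These sizes put binomial noise on the
measured rates well inside the asserted bands.

## Known limitations

- The DMR t-test treats cell fractions as exchangeable observations and
  ignores per-cell coverage differences within a region beyond the
  qualifying-CpG filter; a beta-binomial regression would weight cells
  properly but is out of scope.
- The NB Wald test has no outlier moderation; a single extreme cell can
  drive a call at these group sizes.
- The joint NMF is not identifiable up to factor permutation; only the
  induced partition (and marker sets per factor) are stable across
  seeds.
- Raw-p DMR calling (no FDR) reproduces the source protocol and
  therefore inherits its multiplicity behavior: at 3 000 windows,
  ~150 raw-p false positives are expected and observed on null data.
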