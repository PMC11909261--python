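# Methods

## Problem setting

A target GWAS reports only per-SNP P values (typical of multivariate shape
phenotypes, whose test statistic is an unsigned quadratic form), and one or
more auxiliary GWAS of genetically correlated traits are available. The goal
is to quantify the cross-trait sharing of association signal and to exploit
it: lowering the effective false-discovery rate of target-trait discoveries
by conditioning on the auxiliary P values.

## Estimators

### Cross-trait fold enrichment

At a threshold α (default 0.05 on both traits),
`fold = P̂(p_t < α | p_a < α) / P̂(p_t < α)` computed from direct counts on
the aligned variant set. The ratio is algebraically reciprocal between the
two traits (`fold = n·k / (s·h)` with k the joint count, s and h the two
marginal counts), which the implementation verifies to 1e-12 as a numerical
self-check. The stratified version applies the same ratio within an
annotation's variants (intervals extended by a margin, 10 kb for TF-site /
ATAC tracks); its standard error comes from resampling *intervals* (not
SNPs) with replacement, because intervals are the exchangeable sampling unit
of an annotation track. Replicates with an undefined ratio are dropped and
counted; more than 50% undefined aborts with an error.

An important and easily missed property: the stratified ratio is
**non-monotone in the annotation's causal fraction**. Conditioning both
numerator and denominator on membership removes the null/causal mixture that
generates tail dependence, so a hypothetical annotation containing *only*
causal variants has fold ≈ 1 — below a random annotation. The ratio peaks
when the member causal fraction is of order α divided by the per-causal
power. Real binding-site tracks are dilute (causal variants are a small
minority of member SNPs), which is the regime where a causal-capturing track
scores above decoys; the synthetic annotation generator therefore defaults
to a dilute track (decoy_rate 0.15 of non-causal variants alongside the
captured causals).

### Genomic correlation without signed effects

Per LD block, the mean of −log₁₀ P is computed for each trait over member
variants (after removing the MHC chr6:25,119,106–33,854,733 and
chr8:7,200,000–12,500,000 exclusion regions, GRCh37); the genomic
correlation is the Spearman rank correlation of the two block-mean vectors,
with average ranks for ties. A `literal_formula` flag evaluates the
rank-difference expression `1 − 6·Σdᵢ/(n(n²−1))` with *unsquared* dᵢ; with
average ranks Σdᵢ = 0 identically, so that variant degenerates to 1 — it is
retained only to document the difference from standard Spearman (which
squares dᵢ) and is not the default.

### Conditional Q-Q curves

For each auxiliary threshold q\* (defaults 1, 0.1, 0.01, 0.001 — nested
strata spanning the conventional conditional-QQ range), variants with
p_a ≤ q\* contribute observed quantiles (sorted −log₁₀ p_t) against expected
−log₁₀ of uniform order statistics i/(n+1). Curves are thinned to a point
budget by quantile subsampling; empty strata are skipped with a warning.

### Conservative conditional FDR

`cFDR(p_t|p_a) = π₀(p_a)·F₀(p_t|p_a)/F(p_t|p_a)` with the conservative
substitutions π₀ = 1 and F₀(p_t|p_a) = p_t (null independence), and F the
empirical conditional CDF. Per variant this is

```
cFDR_i = p_t,i · #{j: p_a,j ≤ p_a,i} / #{j: p_t,j ≤ p_t,i and p_a,j ≤ p_a,i}
```

capped at 1 (`brute_force_cfdr`, the quadratic-time reference). With p_a ≡ 1
the conditioning set is the whole sample and the estimator reduces exactly
to the empirical-Bayes FDR `min(1, p·n/rank)` with max-rank ties.

**LD de-biasing.** Long haplotypes over-weight the empirical CDF, so the
model is fitted on randomly LD-pruned subsets: each iteration keeps a random
maximal subset with pairwise r² < 0.2 (default; 500 iterations), and the
bivariate histogram of (−log₁₀ p_t, −log₁₀ p_a) over kept variants is
averaged across iterations. Averaging *counts* rather than per-iteration
cFDRs yields a single well-defined empirical CDF. The pruning rule — visit
variants in random order, keep unless a kept neighbor has r² at or above the
threshold — is implemented as a priority-based parallel maximal-independent-
set selection, which provably yields the same subset as the sequential
greedy pass but vectorizes to 10⁵-variant instances.

**Grid and post-processing.** The estimator is evaluated on a −log₁₀ grid:
step 0.1 from 0 to 10 (dense where decisions happen), step 1 from 10 to 300
(bounded memory; P values are floored at 1e-300 so transforms stay finite).
Because the histogram bin edges coincide with the grid, the suffix-cumulated
averaged counts give the estimator *exactly* at every grid node — the
surface equals the brute-force estimator at grid resolution, which the test
suite checks by snapping data to the grid. Values are capped at 1 and then
monotonized along the target axis with a cumulative minimum (the raw
estimator is non-monotone because counts change in steps while the p_t
factor moves continuously); cap-then-monotonize order means monotonization
can only lower values, preserving conservatism relative to the raw
estimator. Per-SNP lookup is bilinear interpolation on the grid with
clamping at the boundaries — queries more significant than the grid maximum
return the boundary value rather than extrapolating below the fitted
minimum. Nodes beyond the observed data (zero joint count) inherit the last
fitted value through the cumulative minimum.

### Loci and expected false discoveries

Variants below the cFDR/FDR threshold are visited in increasing value order
(ties broken by chromosome then position, making the procedure independent
of input row order). A variant becomes a lead unless it has r² ≥ 0.1 with an
existing lead (LD lookups beyond 1 Mb are taken as r² = 0; absent pairs
count as 0); otherwise it joins the first such lead's clump. Leads within
250 kb on the same chromosome are merged — transitively, since the
definition of "within 250 kb" chains — into one locus represented by the
most significant lead, spanning all clumped members. Cross-analysis merging
pools leads from several conditioned analyses under the same 250 kb rule and
records each locus's source set. The expected number of false discoveries at
a threshold is the sum of lead cFDR values below it, summed across analyses
*without* deduplication — valid because the cFDR is a posterior null
probability, and deliberately conservative under dependence between
analyses.

## The synthetic study

The generator emulates the statistical structure the method consumes, with
defaults chosen once as study-like conditions:

| parameter | default | meaning |
|---|---|---|
| n_blocks × block_size | 1725 × 12 | LD blocks (the canonical European block count) × variants per block |
| within_block_r | 0.9 | AR(1) signed correlation between adjacent variants; r² at lag d is r^2d; blocks ≥ 1 Mb apart |
| n_target, n_aux | 6772, 19644 | effective sample sizes (a vault-shape-scale target, brain-shape-scale auxiliary) |
| pi_shared / pi_target_only / pi_aux_only | 0.02 / 0.01 / 0.01 | causal-mixture fractions |
| h2_target, h2_aux | 0.5 | variance explained by causal effects (multivariate-shape-trait scale) |
| rho_shared | 0.8 | correlation of effect sizes at shared causals |
| target_df | 4 | chi-square df of the unsigned multivariate target statistic |

Effects are i.i.d. normal per causal variant, scaled so the expected
per-causal non-centrality is h2·n/m_causal; marginal z statistics are
√n·R·β plus AR(1)-correlated noise (R the block correlation); the target
statistic sums target_df independent replicates of z² with the
non-centrality split across them, so the total is preserved and the null is
exactly central chi-square. The auxiliary trait is a single signed z with
two-sided P. One root seed fans out through fixed named substreams, so
outputs are bit-identical per seed and adding a stage never perturbs
another. The annotation generator covers a chosen fraction of shared-causal
variants plus a decoy fraction of the rest with ±500 bp intervals.

Not modeled, deliberately: allele frequencies and MAF-dependent power,
selection, population structure, cross-cohort sample overlap, signed-effect
output for the target trait, and realistic genome-wide LD beyond
block-diagonal AR(1). Passing tests therefore demonstrate the estimators'
contracts and calibration under a clean two-trait architecture — not
robustness to confounding or to misspecified LD references on real data.

When tests shrink the variant count they rescale h2 to preserve the default
per-causal non-centrality (helper in `tests/conftest.py`); keeping h2 fixed
while shrinking the genome would concentrate the same heritability into ~30×
stronger per-variant signals and silently change the statistical regime.

## Calibration and scoring conventions

A called locus is scored a true positive iff its span contains at least one
target-causal variant; block-level power is the fraction of causal blocks
containing a lead SNP. The span rule is strict: a locus led by an LD
neighbor of a causal variant whose clump does not cover the causal position
counts as false even though its lead is marginally non-null, so the
realized span-based FDP under strong signal exceeds the nominal cFDR level
(which bounds discoveries of *marginally null* SNPs). Under the global null
every called locus is false in both senses, and there the realized
locus-level FDP at 1% cFDR is ~0, with the expected-false-discovery sum
upper-bounding the realized false-positive count — the calibration the test
suite verifies over 50 replicates of 10⁵ variants.

Problem sizes used by the test suite and acceptance script: the headline
run uses the default 20,700-variant study with 500 pruning iterations;
replicate batches (null calibration, power gain) use 20 pruning iterations
per replicate — the averaged-count estimator is identical in expectation and
the batches measure realized discovery behavior, not pruning variance. The
fold-enrichment-under-independence bound (±0.1) is checked per seed at 10⁶
variants, where the estimator's sampling SD is ~2%; at 10⁵ variants the SD
is ~6%, so there the mean over 20 seeds is checked instead.

## Numerical choices and edge cases

* P values: domain (0, 1]; exact zeros rejected at load unless floored
  (default floor 1e-300). P serialized with 17 significant digits so
  round-trips are bit-exact.
* Coordinates: intervals are BED 0-based half-open; variant positions
  1-based; a variant at pos is inside (start, end] after conversion, i.e.
  start < pos ≤ end. Chromosome labels are joined after stripping a leading
  "chr".
* IRLS trend fit: Tukey bisquare weights with tuning constant 4.685 (95%
  Gaussian efficiency), convergence when the max coefficient change drops
  below 1e-8 within 100 iterations (error otherwise, reporting the last
  delta); slope inference from the robust covariance. Implemented on
  statsmodels RLM.
* Annotation-outlier test: the focal annotation's fold is standardized
  against the background annotations' sample mean and SD and referred to a
  Student t with n−1 df, one-tailed upper — a deliberate operationalization
  of "outlier above a fitted background distribution"; with ≥10 background
  values required and a zero-spread background rejected.
* Clump tie-breaks: equal values ordered by (chromosome, position);
  "within 250 kb" merging is inclusive (distance ≤ 250,000 bp) and
  transitive.
* Degenerate inputs raise typed errors (undefined enrichment, insufficient
  blocks/points, empty pruned set, domain violations) rather than returning
  NaN.

## Design decisions that were genuinely open

* Whether the cFDR analysis restricts to the same intersected variant
  universe as the genomic correlation is configurable
  (`restrict_cfdr_to_filter`, default off).
* The gridded surface (resolution, interpolation, monotonization) is an
  implementation choice constrained by the oracle-equivalence tests rather
  than by any published specification of the reference software's
  internals.
* Locus span is the min/max position of clumped members rather than a fixed
  ±window: loci are reported, not windows.
* The merged-locus member count sums the member counts of the merged leads
  (an upper bound when clumps overlap).
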