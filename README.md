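# pleiocfdr

Pleiotropy-informed GWAS discovery from **P-value-only** summary statistics.

Multivariate-shape GWAS (faces, brains, cranial vaults, ...) report a single
unsigned P value per SNP, so the standard toolbox for leveraging genetically
correlated traits — LD-score-regression genetic correlation, MTAG-style
meta-analysis — does not apply. `pleiocfdr` implements the inference chain
that works in this regime:

* **Cross-trait fold enrichment** of association at threshold α (default 0.05):

  ```
  fold = Prob(P_target < α | P_aux < α) / Prob(P_target < α)
  ```

  reciprocal between the traits by Bayes' theorem (checked numerically), with
  an annotation-stratified variant (TF binding sites / ATAC peaks, ±10 kb
  margins) and interval-bootstrap standard errors.

* **Genomic Spearman correlation**: the rank correlation of LD-block-averaged
  −log₁₀ P between two GWAS — a genetic-overlap measure that needs no signed
  effects.

* **Conditional Q-Q curves**: target-trait quantiles within nested auxiliary
  P-value strata; leftward deflection of stricter strata signals shared
  architecture.

* **Conservative conditional FDR (cFDR)**: the posterior probability that a
  SNP is null for the target trait given both observed P values,

  ```
  cFDR(p_t | p_a) = π₀ · F₀(p_t | p_a) / F(p_t | p_a)
  ```

  estimated conservatively with π₀ = 1, F₀(p_t|p_a) = p_t, and F the
  empirical conditional CDF averaged over 500 random LD-pruning iterations
  (r² < 0.2), after excluding the MHC and 8p23.1 long-range-LD regions. With
  an uninformative auxiliary trait this reduces exactly to the
  empirical-Bayes FDR, `p·n/rank(p)`.

* **Locus calling**: greedy lead-SNP clumping at r² = 0.1, 250 kb merging into
  independent loci, cross-analysis merging, and the conservative
  expected-false-discovery count (the sum of lead cFDR values below the
  significance threshold).

* A **synthetic two-trait GWAS generator** with block-structured LD (AR(1)
  within blocks), a null/trait-specific/shared causal mixture with
  configurable effect-size correlation, a multivariate-trait chi-square
  target statistic, causal-enriched annotations, and full ground truth — so
  every stage is testable without restricted-access data.

## Worked example

```python
import pleiocfdr as pc
from pleiocfdr.cfdr import build_cfdr_surface, per_snp_cfdr, unconditioned_fdr
from pleiocfdr.io import exclude_rows

cfg = pc.SimulationConfig(seed=11)            # 1725 LD blocks x 12 variants
target, aux, truth = pc.simulate_sumstats(cfg)
ld = pc.simulate_ld_model(cfg)
joined = pc.align_variants([target, aux])
exclusions = pc.default_exclusions()

surface = build_cfdr_surface(joined, ld, n_iter=500, prune_r2=0.2,
                             exclusions=exclusions, seed=cfg.seed)
scored = per_snp_cfdr(exclude_rows(joined, exclusions), surface)
loci = pc.clump(scored, ld, clump_r2=0.1, merge_kb=250, threshold=0.01)
```

Running `python examples/02_conditional_fdr_discovery.py` (exactly the above
plus the unconditioned comparison) prints:

```
loci at 1% cFDR (conditioned):    92
loci at 1% FDR (unconditioned):   59
expected false discoveries:       0.163 (sum of lead cFDRs < 0.01)
causal blocks detected:           89 vs 59 (of 516)
realized FDP (span-based):        0.120 vs 0.068
```

Conditioning on the correlated trait finds ~1.6× as many loci at the same
nominal level, detects 50% more truly causal LD blocks, and the
expected-false-discovery sum says fewer than one of the 92 lead SNPs is
expected to be marginally null. `examples/01_cross_trait_enrichment.py` and
`examples/03_annotation_and_trend.py` walk through the enrichment,
correlation, Q-Q, annotation-stratification and trend-fit capabilities the
same way.

A thin CLI mirrors the library:

```bash
pleio-cfdr simulate --seed 3 --out sim/
pleio-cfdr enrich sim/target.sumstats.tsv sim/aux.sumstats.tsv
pleio-cfdr cfdr sim/target.sumstats.tsv sim/aux.sumstats.tsv sim/ld_pairs.tsv --out-prefix run
pleio-cfdr run config.yaml      # full pipeline from one YAML config
```

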