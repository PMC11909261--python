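"""Conditional-FDR discovery versus the unconditioned analysis.

Fits the conservative cFDR surface from randomly LD-pruned empirical counts,
assigns per-SNP cFDR values, clumps independent loci at 1% cFDR, and compares
against loci from the unconditioned empirical-Bayes FDR — with ground truth
to score both.
"""

import pleiocfdr as pc
from pleiocfdr.cfdr import build_cfdr_surface, per_snp_cfdr, unconditioned_fdr
from pleiocfdr.io import exclude_rows

cfg = pc.SimulationConfig(seed=11)
target, aux, truth = pc.simulate_sumstats(cfg)
ld = pc.simulate_ld_model(cfg)
joined = pc.align_variants([target, aux])
exclusions = pc.default_exclusions()  # MHC + 8p23.1 long-range LD

surface = build_cfdr_surface(
    joined, ld, n_iter=500, prune_r2=0.2, exclusions=exclusions, seed=cfg.seed
)
base = exclude_rows(joined, exclusions)
scored = per_snp_cfdr(base, surface)
conditioned = pc.clump(scored, ld, clump_r2=0.1, merge_kb=250, threshold=0.01)

uncond = base.copy()
uncond["fdr"] = unconditioned_fdr(uncond["p_target"].to_numpy())
unconditioned = pc.clump(uncond, ld, threshold=0.01, value_col="fdr")

efd = pc.expected_false_discoveries([conditioned], threshold=0.01)
sc_c = pc.score_against_truth(conditioned, truth)
sc_u = pc.score_against_truth(unconditioned, truth)

print(f"loci at 1% cFDR (conditioned):    {sc_c.n_loci}")
print(f"loci at 1% FDR (unconditioned):   {sc_u.n_loci}")
print(f"expected false discoveries:       {efd:.3f} (sum of lead cFDRs < 0.01)")
print(f"causal blocks detected:           {sc_c.n_detected_blocks} vs "
      f"{sc_u.n_detected_blocks} (of {sc_c.n_causal_blocks})")
print(f"realized FDP (span-based):        {sc_c.fdp:.3f} vs {sc_u.fdp:.3f}")
print("\nConditioning on a genetically correlated trait raises the number of")
print("discovered loci at the same nominal cFDR level; the expected-false-")
print("discovery sum stays far below one false locus.")
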