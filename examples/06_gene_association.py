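"""Silencing-vs-expression association at gene level.

Runs the pipeline with zero expression coupling (the generator's null) and
prints the association report: with no true coupling the correlation between
per-gene silencing divergence and expression divergence should sit near 0.
"""

from orthosilence import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(simulation=SimulationConfig(
    seed=8, n_chrom=1, chrom_len=400_000, n_te=900,
    n_individuals_per_species=(5, 4), n_genes=200, expression_coupling=0.0))
res = run_pipeline(cfg)
assoc = res.association

print(f"genes with both silencing and expression results: {assoc['n_genes']}")
print("expression log2fc by upstream-silencing category:")
for cat, d in sorted(assoc["expression_lfc_by_silencing_category"].items()):
    print(f"  {cat:12s}: n={d['n']:4d} median log2fc {d['median']:+.3f}")
print("pairwise rank-sum p:", {k: round(v, 3)
                               for k, v in assoc["category_rank_sum_p"].items()})
print(f"silencing vs expression divergence: r = {assoc['pearson_r']:+.3f}, "
      f"permutation p = {assoc['permutation_p']:.3f}")
print(f"sign-consistent gene pairs: {assoc['sign_consistent']}, "
      f"inconsistent: {assoc['sign_inconsistent']}")
# A near-zero r and non-significant contrasts reproduce, as a calibrated
# null, the finding that TE-silencing divergence does not drive expression
# divergence between the species.
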