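"""Simulate a two-species cohort with known ground truth.

Builds a small pair of related genomes (common ancestor, substitutions and
indels, exact chains), TE annotations with silencing labels, per-individual
ChIP/Input fragments and expression counts, then prints what was generated.
"""

from collections import Counter

from orthosilence import SimulationConfig, simulate_cohort

cfg = SimulationConfig(seed=42, n_chrom=1, chrom_len=200_000, n_te=400,
                       n_individuals_per_species=(3, 3), n_genes=60)
cohort = simulate_cohort(cfg)

print(f"genome A: {sum(len(s) for s in cohort.pair.genome_a.values()):,} bp, "
      f"genome B: {sum(len(s) for s in cohort.pair.genome_b.values()):,} bp")
print(f"chain blocks A->B: {sum(len(c.blocks) for c in cohort.pair.chains_ab)}")
print(f"TE annotations: {len(cohort.rmsk_a)} in A, {len(cohort.rmsk_b)} in B")
print("silencing truth:", dict(Counter(
    t.silencing for t in cohort.truth.te_by_uid.values())))
print("orthology truth:", dict(Counter(
    t.orthology for t in cohort.truth.te_by_uid.values())))
n_frags = len(cohort.fragments[("A01", "chip")])
print(f"ChIP fragments for individual A01: {n_frags:,}")
print(f"expression matrix: {cohort.gene_counts.shape[0]} genes x "
      f"{cohort.gene_counts.shape[1]} individuals")
# Each chain block is a run of bases retained contiguously in both species;
# silencing labels are the ground truth the downstream analysis must recover.
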