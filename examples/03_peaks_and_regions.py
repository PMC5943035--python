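"""Broad H3K9me3 peak calling and orthologous region construction.

Calls broad domains per individual with the windowed Poisson caller, builds
the cross-species orthologous region set, counts fragments and applies the
occupancy filter.
"""

from orthosilence import (PipelineConfig, SimulationConfig, call_broad_peaks,
                          build_orthologous_regions, count_fragments_in_regions,
                          filter_regions_by_occupancy, kmer_mappability,
                          simulate_cohort)

cfg = SimulationConfig(seed=3, n_chrom=1, chrom_len=200_000, n_te=400,
                       n_individuals_per_species=(3, 3), n_genes=40)
cohort = simulate_cohort(cfg)
pcfg = PipelineConfig(simulation=cfg)

track_a = kmer_mappability(cohort.pair.genome_a, 50)
track_b = kmer_mappability(cohort.pair.genome_b, 50)
sizes = {"A": cohort.pair.sizes_a, "B": cohort.pair.sizes_b}

peaks = {}
for indiv in cfg.individuals:
    peaks[indiv] = call_broad_peaks(
        cohort.fragments[(indiv, "chip")], cohort.fragments[(indiv, "input")],
        sizes[indiv[0]], window=pcfg.peak_window, gap=pcfg.peak_gap, q_max=0.1,
    )
    print(f"{indiv}: {len(peaks[indiv])} broad domains at q<=0.1")

regions, log = build_orthologous_regions(
    peaks, cohort.species_map, cohort.pair.chains_ab, cohort.pair.chains_ba,
    track_a, track_b,
)
print(f"orthologous regions after reciprocal lifting + mappability: {len(regions)}")
print("exclusion tally:", log)

chip = {i: cohort.fragments[(i, "chip")] for i in cfg.individuals}
matrix = count_fragments_in_regions(regions, chip, cohort.species_map)
retained = filter_regions_by_occupancy(matrix)
print(f"regions with counts in more than half the individuals: "
      f"{len(retained.counts)} of {len(matrix.counts)}")
# Every retained region carries one fragment count per individual in its own
# genome's coordinates; these counts feed the differential NB test.
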