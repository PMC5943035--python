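import io
from collections import Counter

import numpy as np
import pytest
from scipy import stats as sps

from orthosilence import (
    GenomicInterval,
    SimulationConfig,
    lift_interval,
    simulate_chip_fragments,
    simulate_cohort,
    simulate_expression,
    simulate_gene_models,
    simulate_genome_pair,
    simulate_te_annotations,
    write_chain,
)
from orthosilence.io import write_cohort


class TestConfig:
    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(substitution_rate=1.5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(chrom_len=0).validate()
        with pytest.raises(ValueError):
            SimulationConfig(te_class_weights={"SINE": 0.5, "LINE": 0.4}).validate()

    def test_zero_individuals_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_individuals_per_species=(0, 5)).validate()


class TestGenomePair:
    def test_identity_case_without_mutation(self):
        cfg = SimulationConfig(seed=1, n_chrom=1, chrom_len=50_000,
                               substitution_rate=0.0, indel_rate=0.0)
        pair = simulate_genome_pair(cfg)
        assert pair.genome_a == pair.genome_b
        (chain,) = pair.chains_ab
        assert chain.blocks == [(50_000, 0, 0)]

    def test_substitutions_only_keep_single_block(self):
        cfg = SimulationConfig(seed=2, n_chrom=1, chrom_len=50_000,
                               substitution_rate=0.02, indel_rate=0.0)
        pair = simulate_genome_pair(cfg)
        assert pair.genome_a != pair.genome_b
        assert len(pair.genome_a["chr1"]) == len(pair.genome_b["chr1"])
        assert pair.chains_ab[0].blocks == [(50_000, 0, 0)]

    def test_chain_blocks_match_coordinate_map_oracle(self):
        cfg = SimulationConfig(seed=3, n_chrom=1, chrom_len=80_000, indel_rate=5e-4)
        pair = simulate_genome_pair(cfg)
        n_indels = sum(1 for e in pair.events if e["type"] in ("ins", "del"))
        assert n_indels > 0
        (chain,) = pair.chains_ab
        # independent oracle: recompute aligned runs directly from the
        # ancestor->descendant maps
        map_a = pair.anc_maps["chr1"]["A"]
        map_b = pair.anc_maps["chr1"]["B"]
        aligned = np.flatnonzero((map_a >= 0) & (map_b >= 0))
        da, db = map_a[aligned], map_b[aligned]
        runs = 1 + int(np.sum((np.diff(aligned) != 1) | (np.diff(da) != 1)
                              | (np.diff(db) != 1)))
        assert len(chain.blocks) == runs
        assert sum(b[0] for b in chain.blocks) == aligned.size
        # every indel can break at most one run
        assert runs <= 1 + n_indels

    def test_chain_inversion_is_exact(self):
        cfg = SimulationConfig(seed=4, n_chrom=1, chrom_len=60_000, indel_rate=5e-4)
        pair = simulate_genome_pair(cfg)
        fwd, rev = pair.chains_ab[0], pair.chains_ba[0]
        assert rev.invert().blocks == fwd.blocks
        assert rev.src_start == fwd.tgt_start

    def test_seed_determinism_bytes(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_chrom=1, chrom_len=40_000)
        outputs = []
        for run in range(2):
            pair = simulate_genome_pair(cfg)
            buf = io.StringIO()
            for chrom in sorted(pair.genome_a):
                buf.write(pair.genome_a[chrom])
                buf.write(pair.genome_b[chrom])
            path = tmp_path / f"run{run}.chain"
            write_chain(pair.chains_ab, path)
            outputs.append((buf.getvalue(), path.read_bytes()))
        assert outputs[0] == outputs[1]


@pytest.fixture(scope="module")
def cohort_parts():
    cfg = SimulationConfig(seed=6, n_chrom=1, chrom_len=600_000, n_te=1500)
    pair = simulate_genome_pair(cfg)
    rmsk_a, rmsk_b, truth = simulate_te_annotations(cfg, pair)
    return cfg, pair, rmsk_a, rmsk_b, truth


class TestTEAnnotations:
    def test_orthologous_te_coordinates_correspond_under_chain(self, cohort_parts):
        cfg, pair, rmsk_a, rmsk_b, truth = cohort_parts
        checked = 0
        for t in truth.te_by_uid.values():
            if t.orthology != "orthologous":
                continue
            lifted = lift_interval(t.te_a.interval, pair.chains_ab, min_match=1.0)
            assert lifted is not None
            assert (lifted.start, lifted.end) == (
                t.te_b.interval.start, t.te_b.interval.end)
            checked += 1
        assert checked > 500

    def test_class_proportions_within_three_se(self, cohort_parts):
        cfg, _, _, _, truth = cohort_parts
        counts = Counter(t.te_class for t in truth.te_by_uid.values())
        n = sum(counts.values())
        for cls, w in cfg.te_class_weights.items():
            se = np.sqrt(w * (1 - w) / n)
            assert abs(counts[cls] / n - w) <= 3 * se

    def test_silencing_and_orthology_frequencies_within_three_se(self, cohort_parts):
        cfg, _, _, _, truth = cohort_parts
        tes = list(truth.te_by_uid.values())
        n = len(tes)
        single = sum(1 for t in tes if t.orthology != "orthologous")
        rate = cfg.species_specific_te_rate
        assert abs(single / n - rate) <= 3 * np.sqrt(rate * (1 - rate) / n)
        # shared fraction among silenced orthologous TEs
        sil = [t for t in tes if t.orthology == "orthologous" and t.silencing != "none"]
        shared = sum(1 for t in sil if t.silencing == "shared")
        p = cfg.shared_fraction
        assert abs(shared / len(sil) - p) <= 3 * np.sqrt(p * (1 - p) / len(sil))
        # per-class silencing priors
        for cls, prior in cfg.te_silencing_prior.items():
            cls_tes = [t for t in tes if t.te_class == cls]
            if len(cls_tes) < 30:
                continue
            frac = np.mean([t.silencing != "none" for t in cls_tes])
            se = np.sqrt(prior * (1 - prior) / len(cls_tes))
            assert abs(frac - prior) <= 3 * se + 1e-9

    def test_zero_species_specific_rate_shares_all_names(self):
        cfg = SimulationConfig(seed=7, n_chrom=1, chrom_len=300_000, n_te=400,
                               species_specific_te_rate=0.0)
        pair = simulate_genome_pair(cfg)
        rmsk_a, rmsk_b, truth = simulate_te_annotations(cfg, pair)
        names_a = {t.name for t in rmsk_a}
        names_b = {t.name for t in rmsk_b}
        assert names_a == names_b
        assert all(t.orthology == "orthologous" for t in truth.te_by_uid.values())

    def test_zero_sva_weight_gives_no_sva_rows(self):
        cfg = SimulationConfig(
            seed=8, n_chrom=1, chrom_len=300_000, n_te=400,
            te_class_weights={"SINE": 0.4, "LINE": 0.35, "LTR": 0.15, "DNA": 0.1,
                              "SVA": 0.0},
        )
        pair = simulate_genome_pair(cfg)
        rmsk_a, rmsk_b, _ = simulate_te_annotations(cfg, pair)
        assert all(t.te_class != "SVA" for t in rmsk_a + rmsk_b)

    def test_millidiv_in_bounds_and_silenced_younger(self, cohort_parts):
        _, _, rmsk_a, rmsk_b, truth = cohort_parts
        assert all(0 <= t.milli_div <= 400 for t in rmsk_a + rmsk_b)
        sil = [t.te_a.milli_div for t in truth.te_by_uid.values()
               if t.silencing != "none" and t.te_a]
        unsil = [t.te_a.milli_div for t in truth.te_by_uid.values()
                 if t.silencing == "none" and t.te_a]
        assert np.median(sil) < np.median(unsil)


class TestChipFragments:
    def test_no_silencing_means_background_only(self):
        cfg = SimulationConfig(
            seed=9, n_chrom=1, chrom_len=200_000, n_te=300,
            te_silencing_prior={c: 0.0 for c in ("SINE", "LINE", "LTR", "DNA", "SVA")},
            n_individuals_per_species=(2, 2),
        )
        pair = simulate_genome_pair(cfg)
        _, _, truth = simulate_te_annotations(cfg, pair)
        frags, _ = simulate_chip_fragments(cfg, pair, truth)
        chip = np.array([(f.start + f.end) / 2 for f in frags[("A01", "chip")]])
        inp = np.array([(f.start + f.end) / 2 for f in frags[("A01", "input")]])
        _, p = sps.ks_2samp(chip, inp)
        assert p > 0.01

    def test_shared_silenced_te_enriched_in_both_species(self):
        cfg = SimulationConfig(seed=10, n_chrom=1, chrom_len=300_000, n_te=400,
                               n_individuals_per_species=(3, 3))
        pair = simulate_genome_pair(cfg)
        _, _, truth = simulate_te_annotations(cfg, pair)
        frags, _ = simulate_chip_fragments(cfg, pair, truth)
        shared = [t for t in truth.te_by_uid.values() if t.silencing == "shared"]
        assert len(shared) >= 5
        genome_len = 300_000
        for indiv in ("A01", "B01"):
            chip = frags[(indiv, "chip")]
            dens_bg = len(chip) / genome_len
            total_inside = 0
            total_len = 0
            for te in shared:
                iv = te.te_a.interval if indiv[0] == "A" else te.te_b.interval
                total_inside += sum(
                    1 for f in chip
                    if f.chrom == iv.chrom and f.start < iv.end and f.end > iv.start
                )
                total_len += iv.length
            # pooled density over shared-silenced TEs well above background
            assert total_inside / total_len > 2 * dens_bg

    def test_species_specific_density_ratio_tracks_effect_size(self):
        cfg = SimulationConfig(seed=11, n_chrom=2, chrom_len=500_000, n_te=1200,
                               n_individuals_per_species=(5, 5),
                               species_effect_log2fc=2.0, shared_fraction=0.3)
        pair = simulate_genome_pair(cfg)
        _, _, truth = simulate_te_annotations(cfg, pair)
        frags, depths = simulate_chip_fragments(cfg, pair, truth)
        a_only = [t for t in truth.te_by_uid.values()
                  if t.silencing == "speciesA_only" and t.orthology == "orthologous"]
        assert len(a_only) >= 20
        count_a = count_b = 0
        depth_a = depth_b = 0.0
        for indiv in cfg.individuals:
            chip = frags[(indiv, "chip")]
            by_chrom = {}
            for f in chip:
                by_chrom.setdefault(f.chrom, []).append(f)
            for t in a_only:
                iv = t.te_a.interval if indiv[0] == "A" else t.te_b.interval
                inside = sum(1 for f in by_chrom.get(iv.chrom, [])
                             if f.start < iv.end and f.end > iv.start)
                if indiv[0] == "A":
                    count_a += inside
                else:
                    count_b += inside
        n_a = sum(1 for i in cfg.individuals if i[0] == "A")
        n_b = len(cfg.individuals) - n_a
        ratio = (count_a / n_a) / (count_b / n_b)
        assert 2 ** 1.5 <= ratio <= 2 ** 2.5


class TestExpression:
    def test_coupling_minus_one_sets_mean_effect(self):
        cfg = SimulationConfig(seed=12, n_chrom=1, chrom_len=500_000, n_te=1200,
                               n_genes=400, expression_coupling=-1.0,
                               shared_fraction=0.2)
        pair = simulate_genome_pair(cfg)
        _, _, truth = simulate_te_annotations(cfg, pair)
        genes = simulate_gene_models(cfg, pair)
        simulate_expression(cfg, genes, truth)
        coupled = [g for g, e in truth.gene_effect.items() if e in (-1.0, 1.0)]
        assert coupled  # at least some genes sit downstream of specific TEs
        # genes downstream of an A-silenced TE carry exactly coupling * (+1)
        a_down = [e for e in truth.gene_effect.values() if e == -1.0]
        assert a_down

    def test_counts_recover_configured_effects(self):
        cfg = SimulationConfig(seed=13, n_chrom=1, chrom_len=400_000, n_te=900,
                               n_genes=300, expression_coupling=0.0)
        pair = simulate_genome_pair(cfg)
        _, _, truth = simulate_te_annotations(cfg, pair)
        genes = simulate_gene_models(cfg, pair)
        counts, te_types, totals = simulate_expression(cfg, genes, truth)
        assert counts.shape == (300, 17)
        # realized per-gene species log2 ratios track the configured effects
        a_cols = [c for c in counts.columns if c.startswith("A")]
        b_cols = [c for c in counts.columns if c.startswith("B")]
        ratio = np.log2((counts[a_cols].mean(axis=1) + 1)
                        / (counts[b_cols].mean(axis=1) + 1))
        eff = np.array([truth.gene_effect[g] for g in counts.index])
        slope = np.polyfit(eff, ratio, 1)[0]
        assert 0.7 <= slope <= 1.3
        assert set(totals) == {"A", "B"}
        assert (te_types["length"] > 0).all()


class TestCohortDeterminism:
    def test_written_artifacts_are_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=14, n_chrom=1, chrom_len=120_000, n_te=200,
                               n_individuals_per_species=(2, 2), n_genes=40)
        digests = []
        for run in range(2):
            out = tmp_path / f"run{run}"
            write_cohort(simulate_cohort(cfg), out)
            digest = {}
            for path in sorted(out.rglob("*")):
                if path.is_file():
                    digest[path.relative_to(out).as_posix()] = path.read_bytes()
            digests.append(digest)
        assert digests[0] == digests[1]
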