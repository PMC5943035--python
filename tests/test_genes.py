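import numpy as np
import pandas as pd
import pytest

from orthosilence import (
    CountMatrix,
    GeneModel,
    GenomicInterval,
    differential_expression,
    filter_and_normalize_expression,
    gene_set_h3k9me3_overlap,
    gene_silencing_counts,
    select_tss,
    silencing_expression_association,
    te_type_rpkm,
    upstream_window,
)
from orthosilence.peaks import OrthologousRegion
from orthosilence.silencing import SilencedTECall
from orthosilence.stats import DifferentialResult
from orthosilence.repeats import TEInstance

from conftest import nb_matrix


class TestTSS:
    def test_sense_strand_takes_five_prime_most(self):
        assert select_tss([(100, 500), (150, 600)], "+") == 100

    def test_antisense_strand_takes_three_prime_most(self):
        assert select_tss([(100, 500), (150, 600)], "-") == 150

    def test_single_transcript(self):
        assert select_tss([(42, 100)], "+") == 42

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_tss([], "+")


class TestUpstreamWindow:
    def test_plus_strand(self):
        w = upstream_window(5000, "+", 1000, 100_000, "chr1")
        assert (w.start, w.end) == (4000, 5000)

    def test_minus_strand(self):
        w = upstream_window(5000, "-", 1000, 100_000, "chr1")
        assert (w.start, w.end) == (5000, 6000)

    def test_clipped_at_chrom_start(self):
        w = upstream_window(500, "+", 1000, 100_000, "chr1")
        assert (w.start, w.end) == (0, 500)

    def test_tss_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            upstream_window(200_000, "+", 1000, 100_000)

    def test_windows_exclude_tss_base(self):
        for strand in "+-":
            w = upstream_window(5000, strand, 1000, 100_000)
            if strand == "+":
                assert w.end == 5000
            else:
                assert w.start == 5000


class TestGeneSilencingCounts:
    def _setup(self):
        genes = [
            GeneModel("g1", "chr1", "+", [(20_000, 30_000)]),
            GeneModel("g2", "chr1", "+", [(60_000, 70_000)]),
            GeneModel("g3", "chr1", "+", [(90_000, 95_000)]),
        ]
        cols = [f"i{k}" for k in range(8)]
        species = {c: ("A" if i < 4 else "B") for i, c in enumerate(cols)}

        def te(start, end, rid):
            t = TEInstance(GenomicInterval("chr1", start, end, "+"), "AluY", "Alu",
                          "SINE", 100.0, "A")
            status = "shared" if rid else "non_overlapping"
            return SilencedTECall(t, 1.0 if rid else 0.0, status, rid)

        # g1 window [10k,20k): two TEs in one region R0 + one TE in R1
        # g2 window [50k,60k): one TE with no region
        # g3 window [80k,90k): no TEs -> omitted
        calls = [te(11_000, 11_300, "R0"), te(12_000, 12_300, "R0"),
                 te(15_000, 15_300, "R1"), te(55_000, 55_300, None)]
        regions = [
            OrthologousRegion("R0", GenomicInterval("chr1", 10_800, 12_500),
                              GenomicInterval("chr1", 10_800, 12_500), 1.0, 1.0),
            OrthologousRegion("R1", GenomicInterval("chr1", 14_900, 15_400),
                              GenomicInterval("chr1", 14_900, 15_400), 1.0, 1.0),
        ]
        counts = pd.DataFrame(
            {c: [10 * (i + 1), 3 * (i + 1)] for i, c in enumerate(cols)},
            index=["R0", "R1"],
        )
        matrix = CountMatrix(counts, species)
        return genes, calls, regions, matrix

    def test_region_counted_once_and_sums_match_hand_tally(self):
        genes, calls, regions, matrix = self._setup()
        summaries = gene_silencing_counts(
            genes, 10_000, calls, regions, matrix, {"chr1": 200_000}
        )
        by_id = {s.gene_id: s for s in summaries}
        # g1: R0 once + R1 once, despite two TEs in R0
        assert by_id["g1"].n_regions_used == 2
        expected = matrix.counts.loc["R0"] + matrix.counts.loc["R1"]
        assert by_id["g1"].counts == {k: int(v) for k, v in expected.items()}
        # g2 has a TE but no region -> zero counts, no differential result
        assert by_id["g2"].n_regions_used == 0
        assert by_id["g2"].diff is None
        # g3 has no TE in its window -> omitted entirely
        assert "g3" not in by_id


class TestExpressionFilter:
    def test_seventeen_individual_boundary(self):
        cols = [f"i{k}" for k in range(17)]
        row_keep = [1] * 11 + [0] * 6
        row_drop = [1] * 10 + [0] * 7
        df = pd.DataFrame([row_keep, row_drop, [5] * 17],
                          index=["keep", "drop", "high"], columns=cols)
        species = {c: ("A" if i < 10 else "B") for i, c in enumerate(cols)}
        filtered, _ = filter_and_normalize_expression(df, species)
        assert "keep" in filtered.index
        assert "drop" not in filtered.index

    def test_identical_columns_are_fixed_point(self):
        cols = ["a", "b", "c", "d"]
        df = pd.DataFrame({c: [10, 40, 90, 160] for c in cols})
        species = {"a": "A", "b": "A", "c": "B", "d": "B"}
        filtered, norm = filter_and_normalize_expression(df, species)
        # quantile normalization maps identical columns to themselves (then
        # cpm+log2); all columns stay identical
        assert (norm.nunique(axis=1) == 1).all()

    def test_quantile_fixture_hand_computed(self):
        # columns [1,2,3] and [4,5,6]: order-statistic means are [2.5,3.5,4.5]
        df = pd.DataFrame({"a": [1, 2, 3], "b": [4, 5, 6],
                           "c": [1, 2, 3], "d": [4, 5, 6]})
        species = {"a": "A", "b": "A", "c": "B", "d": "B"}
        _, norm = filter_and_normalize_expression(df, species)
        ref = np.array([2.5, 3.5, 4.5])
        cpm = ref / ref.sum() * 1e6
        expected = np.log2(cpm + 1)
        for col in df.columns:
            assert np.allclose(norm[col], expected)


class TestDifferentialExpression:
    def test_all_identical_matrix_no_calls(self):
        cols = [f"i{k}" for k in range(8)]
        df = pd.DataFrame({c: [50] * 30 for c in cols})
        species = {c: ("A" if i < 4 else "B") for i, c in enumerate(cols)}
        res = differential_expression(df, species)
        assert all(r.category == "shared" for r in res)

    def test_twofold_effect_recovered(self):
        rng = np.random.default_rng(0)
        df, species = nb_matrix(rng, 600, 8, 8, alpha=0.1, effect_rows=100,
                                balanced=True)
        res = differential_expression(df, species)
        lfc = np.array([abs(r.log2fc) for r in res[:100] if r.tested])
        assert abs(lfc.mean() - 1.0) < 0.15


class TestAssociation:
    def _res(self, fid, lfc, cat):
        r = DifferentialResult(fid, 100, lfc, 0.2, 0.01, padj=0.01)
        r.category = cat
        return r

    def test_gene_missing_from_one_input_excluded(self):
        sil = {"g1": self._res("g1", 1.0, "A_enriched"),
               "g2": self._res("g2", 0.0, "shared"),
               "g3": self._res("g3", -0.5, "shared")}
        de = {"g1": self._res("g1", -1.2, "B_enriched"),
              "g2": self._res("g2", 0.1, "shared"),
              "g3": self._res("g3", 0.4, "shared"),
              "g9": self._res("g9", 2.0, "A_enriched")}
        out = silencing_expression_association(sil, de, n_perm=99, seed=0)
        assert out["n_genes"] == 3

    def test_sign_consistency_counts(self):
        sil = {f"g{i}": self._res(f"g{i}", lfc, "shared")
               for i, lfc in enumerate([2.0, -1.5, 1.2, 0.1])}
        de = {f"g{i}": self._res(f"g{i}", lfc, "shared")
              for i, lfc in enumerate([-1.1, 1.4, 1.3, 5.0])}
        out = silencing_expression_association(sil, de, n_perm=99, seed=0)
        # g0: +/-, g1: -/+ -> consistent; g2: +/+ -> inconsistent; g3 below threshold
        assert out["sign_consistent"] == 2
        assert out["sign_inconsistent"] == 1

    def test_negative_coupling_detected(self):
        rng = np.random.default_rng(1)
        sil, de = {}, {}
        for i in range(300):
            s = rng.normal(0, 1.2)
            e = -0.8 * s + rng.normal(0, 0.5)
            sil[f"g{i}"] = self._res(f"g{i}", s, "shared")
            de[f"g{i}"] = self._res(f"g{i}", e, "shared")
        out = silencing_expression_association(sil, de, n_perm=999, seed=2)
        assert out["pearson_r"] < -0.5
        assert out["permutation_p"] < 0.01


class TestNonOrthologousAssociation:
    def test_silent_labelling_and_exclusions(self):
        from conftest import identity_chain
        from orthosilence import nonorthologous_te_association

        chain = identity_chain(size=200_000)
        genes = [GeneModel("g1", "chr1", "+", [(50_000, 60_000)]),
                 GeneModel("g2", "chr1", "+", [(120_000, 130_000)]),
                 GeneModel("g3", "chr1", "+", [(160_000, 170_000)])]

        def te(start, end):
            return TEInstance(GenomicInterval("chr1", start, end, "+"), "AluYa5",
                              "Alu", "SINE", 30.0, "A")

        # g1 window [40k,50k): one TE fully inside a peak -> silent
        # g2 window [110k,120k): two TEs, one unmarked -> non_silent
        # g3 window [150k,160k): no TEs -> excluded from the report
        tes = {"A": [te(42_000, 42_300), te(112_000, 112_300),
                     te(115_000, 115_300)],
               "B": []}
        peaks = {"A": [GenomicInterval("chr1", 41_900, 42_400),
                       GenomicInterval("chr1", 111_900, 112_400)],
                 "B": []}
        de = {}
        for i, (gid, lfc) in enumerate([("g1", 0.4), ("g2", -0.6), ("g3", 1.0)]):
            de[gid] = DifferentialResult(gid, 100, lfc, 0.2, 0.5, padj=0.5)
        report = nonorthologous_te_association(
            tes, peaks, genes, [10_000], de, [chain], [chain.invert()],
            {"A": {"chr1": 200_000}, "B": {"chr1": 200_000}},
        )
        row = report[(report.species == "A") & (report.window == 10_000)].iloc[0]
        assert row["n_silent"] == 1
        assert row["n_non_silent"] == 1
        # with fewer than 2 genes per label the contrast is skipped
        assert np.isnan(row["rank_sum_p"])


class TestRPKM:
    def test_worked_arithmetic(self):
        df = te_type_rpkm(
            {"A": {"SVA_A": 5000, "AluY": 500}},
            {"A": {"SVA_A": 250_000, "AluY": 250_000}},
            {"A": 10_000_000},
        ).set_index("te_type")
        assert df.loc["SVA_A", "rpkm"] == pytest.approx(2.0)
        assert bool(df.loc["SVA_A", "expressed"])
        assert df.loc["AluY", "rpkm"] == pytest.approx(0.2)
        assert not df.loc["AluY", "expressed"]

    def test_rpkm_exactly_one_not_expressed(self):
        df = te_type_rpkm({"A": {"X": 2500}}, {"A": {"X": 250_000}}, {"A": 10_000_000})
        assert df["rpkm"].iloc[0] == pytest.approx(1.0)
        assert not bool(df["expressed"].iloc[0])

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            te_type_rpkm({"A": {"X": 10}}, {"A": {"X": 0}}, {"A": 1000})


class TestGeneSetOverlap:
    def _genes(self):
        return [GeneModel("g1", "chr1", "+", [(10_000, 14_000)]),
                GeneModel("g2", "chr1", "+", [(50_000, 54_000)])]

    def test_gene_inside_region_hits_both_modes(self):
        regions = [OrthologousRegion("R0", GenomicInterval("chr1", 9_000, 15_000),
                                     GenomicInterval("chr1", 9_000, 15_000), 1, 1)]
        diff = {"R0": DifferentialResult("R0", 10, 0.5, 1, 0.5, padj=0.5)}
        for mode in ("body_half", "tss_1kb_half"):
            table, unknown = gene_set_h3k9me3_overlap(
                ["g1", "gX"], self._genes(), regions, diff, mode)
            assert unknown == ["gX"]
            assert bool(table.set_index("gene_id").loc["g1", "overlapping"])

    def test_tss_window_499_of_1000_misses(self):
        # region covers 499 bp of the 1 kb TSS window [9500, 10500)
        regions = [OrthologousRegion("R0", GenomicInterval("chr1", 9_500, 9_999),
                                     GenomicInterval("chr1", 9_500, 9_999), 1, 1)]
        table, _ = gene_set_h3k9me3_overlap(
            ["g1"], self._genes(), regions, {}, "tss_1kb_half")
        assert not bool(table["overlapping"].iloc[0])
        regions2 = [OrthologousRegion("R0", GenomicInterval("chr1", 9_500, 10_000),
                                      GenomicInterval("chr1", 9_500, 10_000), 1, 1)]
        table2, _ = gene_set_h3k9me3_overlap(
            ["g1"], self._genes(), regions2, {}, "tss_1kb_half")
        assert bool(table2["overlapping"].iloc[0])

    def test_flags_match_brute_force_coverage(self):
        rng = np.random.default_rng(2)
        genes = [GeneModel(f"g{i}", "chr1", "+",
                           [(int(s), int(s) + int(rng.integers(2000, 8000)))])
                 for i, s in enumerate(rng.integers(10_000, 400_000, 50))]
        regions = [OrthologousRegion(f"R{i}", GenomicInterval("chr1", int(s), int(s) + 3000),
                                     GenomicInterval("chr1", int(s), int(s) + 3000), 1, 1)
                   for i, s in enumerate(rng.integers(0, 400_000, 60))]
        table, _ = gene_set_h3k9me3_overlap(
            [g.gene_id for g in genes], genes, regions, {}, "body_half")
        for g in genes:
            covered = set()
            for r in regions:
                lo = max(r.interval_a.start, g.span.start)
                hi = min(r.interval_a.end, g.span.end)
                covered.update(range(lo, max(lo, hi)))
            expected = len(covered) >= 0.5 * g.span.length
            got = bool(table.set_index("gene_id").loc[g.gene_id, "overlapping"])
            assert got == expected
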