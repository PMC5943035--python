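"""Gene-anchored analyses linking TE silencing to expression divergence.

Covers TSS selection (5'-most transcript on the sense strand, 3'-most on the
antisense strand), upstream cis-regulatory windows (1/10/20/40 kb), the
per-gene H3K9me3 TE-silencing count (each orthologous region counted once
per gene window), expression filtering and quantile normalization,
differential expression through the shared NB engine, TE-type RPKM, gene-set
overlap, and the silencing-versus-expression-divergence association.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chainmap import ChainAlignment, LiftFailure, lift_interval, reciprocal_lift
from .core import GenomicInterval, IntervalCoverage
from .peaks import CountMatrix, OrthologousRegion
from .repeats import TEInstance
from .silencing import SilencedTECall
from .stats import (
    DifferentialResult,
    chi_squared_test,
    classify_enrichment,
    estimate_dispersions,
    independent_filter,
    nb_wald_test,
    pearson_corr_permutation,
    rank_sum_test,
    size_factors,
)

__all__ = [
    "GeneModel",
    "GeneSilencingSummary",
    "select_tss",
    "upstream_window",
    "gene_silencing_counts",
    "filter_and_normalize_expression",
    "differential_expression",
    "silencing_expression_association",
    "te_type_rpkm",
    "gene_set_h3k9me3_overlap",
    "nonorthologous_te_association",
]


@dataclass
class GeneModel:
    """A gene with its transcripts and the single representative TSS."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[tuple[int, int]]
    orthologous: bool = True
    tss: int = field(init=False)

    def __post_init__(self) -> None:
        self.tss = select_tss(self.transcripts, self.strand)

    @property
    def span(self) -> GenomicInterval:
        start = min(s for s, _ in self.transcripts)
        end = max(e for _, e in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)


@dataclass
class GeneSilencingSummary:
    gene_id: str
    window_size: int
    counts: dict[str, int]
    n_regions_used: int
    diff: DifferentialResult | None = None


def select_tss(transcripts: Sequence[tuple[int, int]], strand: str) -> int:
    """The 5'-most transcript start for sense-strand genes, the 3'-most for
    antisense-strand genes (both in terms of txStart)."""
    if not transcripts:
        raise ValueError("gene has no transcripts")
    starts = [s for s, _ in transcripts]
    return min(starts) if strand == "+" else max(starts)


def upstream_window(
    tss: int, strand: str, size: int, chrom_len: int, chrom: str = "chr"
) -> GenomicInterval | None:
    """The ``size``-bp window immediately upstream of (and excluding) the TSS
    base, clipped at chromosome ends; ``None`` when clipping empties it."""
    if size <= 0:
        raise ValueError("window size must be positive")
    if not (0 <= tss < chrom_len):
        raise ValueError(f"TSS {tss} outside chromosome of length {chrom_len}")
    if strand == "+":
        start, end = max(0, tss - size), tss
    else:
        start, end = tss, min(chrom_len, tss + size)
    if start >= end:
        return None
    return GenomicInterval(chrom, start, end, strand)


def _fit_nb(
    counts: pd.DataFrame, species: Mapping[str, str], alpha: float
) -> list[DifferentialResult]:
    try:
        sf = size_factors(counts)
    except ValueError:
        # degenerate matrices (no feature positive everywhere): total-count ratio
        totals = counts.sum(axis=0).astype(float)
        sf = totals / np.exp(np.mean(np.log(totals)))
    disp = estimate_dispersions(counts, sf, dict(species))
    results = nb_wald_test(counts, sf, disp, dict(species))
    results = independent_filter(results, alpha=alpha)
    classify_enrichment(results, alpha=alpha)
    return results


def gene_silencing_counts(
    genes: Sequence[GeneModel],
    window_size: int,
    te_calls: Sequence[SilencedTECall],
    regions: Sequence[OrthologousRegion],
    matrix: CountMatrix,
    chrom_sizes: Mapping[str, int],
    alpha: float = 0.01,
) -> list[GeneSilencingSummary]:
    """Per-gene summed H3K9me3 counts over TE-overlapping regions upstream of
    the TSS, with NB differential testing of the summed counts.

    For each gene window the distinct orthologous regions assigned to TEs
    inside the window contribute their per-individual counts exactly once.
    Genes whose window holds TEs but no H3K9me3-marked region are returned
    with zero counts and no differential result; genes without any TE in the
    window are omitted entirely.
    """
    region_rows = {
        rid: matrix.counts.loc[rid]
        for rid in matrix.counts.index
    }
    te_by_chrom: dict[str, list[SilencedTECall]] = defaultdict(list)
    for call in te_calls:
        te_by_chrom[call.interval.chrom].append(call)
    for lst in te_by_chrom.values():
        lst.sort(key=lambda c: c.interval.start)

    summaries: list[GeneSilencingSummary] = []
    rows = {}
    for gene in genes:
        win = upstream_window(
            gene.tss, gene.strand, window_size, chrom_sizes[gene.chrom], gene.chrom
        )
        if win is None:
            continue
        in_window = [
            c
            for c in te_by_chrom.get(gene.chrom, [])
            if c.interval.start < win.end and c.interval.end > win.start
        ]
        if not in_window:
            continue
        rids = sorted(
            {
                c.assigned_region
                for c in in_window
                if c.assigned_region is not None and c.assigned_region in region_rows
            }
        )
        if rids:
            total = sum((region_rows[r] for r in rids[1:]), region_rows[rids[0]])
            counts = {k: int(v) for k, v in total.items()}
            rows[gene.gene_id] = total
        else:
            counts = {k: 0 for k in matrix.counts.columns}
        summaries.append(
            GeneSilencingSummary(gene.gene_id, window_size, counts, len(rids))
        )

    if rows:
        mat = pd.DataFrame(rows).T
        mat.columns = matrix.counts.columns
        n_a = sum(1 for v in matrix.species.values() if v == "A")
        n_b = len(matrix.species) - n_a
        if len(mat) >= 2 and min(n_a, n_b) >= 3:
            results = {r.feature_id: r for r in _fit_nb(mat, matrix.species, alpha)}
            for s in summaries:
                s.diff = results.get(s.gene_id)
    return summaries


def filter_and_normalize_expression(
    gene_counts: pd.DataFrame, species: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Occupancy-filter and quantile-normalize an expression count matrix.

    Genes with nonzero counts in more than ``10/17`` of individuals (the
    threshold scales with cohort size, rounding down) are retained. Counts
    are quantile-normalized across individuals (each column's order
    statistics mapped to the cross-column mean quantile vector; ties share
    average ranks), converted to counts per million and log2-transformed
    with a pseudocount of 1. Returns (filtered raw counts, normalized log2
    expression).
    """
    n = gene_counts.shape[1]
    if n < 4:
        raise ValueError("need at least 4 individuals")
    threshold = math.floor(n * 10 / 17)
    keep = (gene_counts > 0).sum(axis=1) > threshold
    filtered = gene_counts.loc[keep]

    arr = filtered.to_numpy(dtype=float)
    order_stats = np.sort(arr, axis=0)
    reference = order_stats.mean(axis=1)
    from scipy.stats import rankdata

    qn = np.empty_like(arr)
    grid = np.arange(1, arr.shape[0] + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average")
        qn[:, j] = np.interp(ranks, grid, reference)
    cpm = qn / qn.sum(axis=0, keepdims=True) * 1e6
    log2cpm = np.log2(cpm + 1.0)
    norm = pd.DataFrame(log2cpm, index=filtered.index, columns=filtered.columns)
    return filtered, norm


def differential_expression(
    filtered_counts: pd.DataFrame,
    species: Mapping[str, str],
    alpha: float = 0.01,
) -> list[DifferentialResult]:
    """Species differential expression on the filtered raw counts via the
    shared NB engine (categories at the given FDR)."""
    return _fit_nb(filtered_counts, species, alpha)


def silencing_expression_association(
    gene_silencing: Mapping[str, DifferentialResult],
    gene_de: Mapping[str, DifferentialResult],
    n_perm: int = 1000,
    seed: int = 0,
    effect_threshold: float = 1.0,
) -> dict:
    """Associate per-gene TE-silencing divergence with expression divergence.

    Reports (a) expression log2fc distributions per silencing category with
    pairwise rank-sum tests, (b) a silencing-category by DE-status
    cross-tabulation with a chi-squared test, (c) the Pearson correlation of
    silencing vs expression log2fc with a permutation p-value, and (d) counts
    of genes whose two effects (both beyond ``effect_threshold`` in absolute
    value) have opposite signs (consistent with silencing lowering
    expression) vs the same sign.
    """
    shared = sorted(set(gene_silencing) & set(gene_de))
    if not shared:
        raise ValueError("no genes shared between silencing and expression inputs")
    sil = {g: gene_silencing[g] for g in shared}
    de = {g: gene_de[g] for g in shared}

    by_cat: dict[str, list[float]] = defaultdict(list)
    for g in shared:
        if np.isfinite(de[g].log2fc):
            by_cat[sil[g].category].append(de[g].log2fc)
    cat_tests = {}
    cats = sorted(by_cat)
    for i, c1 in enumerate(cats):
        for c2 in cats[i + 1 :]:
            if len(by_cat[c1]) < 2 or len(by_cat[c2]) < 2:
                continue
            _, p = rank_sum_test(by_cat[c1], by_cat[c2])
            cat_tests[f"{c1}_vs_{c2}"] = p

    crosstab: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for g in shared:
        crosstab[de[g].category][sil[g].category] += 1
    sil_cats = sorted({c for row in crosstab.values() for c in row})
    table = [
        [crosstab[de_cat].get(sc, 0) for sc in sil_cats] for de_cat in sorted(crosstab)
    ]
    chi_p = float("nan")
    tab = np.asarray(table)
    if tab.shape[0] >= 2 and tab.shape[1] >= 2 and (tab.sum(0) > 0).all() and (
        tab.sum(1) > 0
    ).all():
        _, _, chi_p = chi_squared_test(tab)

    xs, ys = [], []
    for g in shared:
        if np.isfinite(sil[g].log2fc) and np.isfinite(de[g].log2fc):
            xs.append(sil[g].log2fc)
            ys.append(de[g].log2fc)
    if len(xs) >= 3 and np.ptp(xs) > 0 and np.ptp(ys) > 0:
        r, perm_p = pearson_corr_permutation(xs, ys, n_perm=n_perm, seed=seed)
    else:
        r, perm_p = float("nan"), float("nan")

    consistent = inconsistent = 0
    for x, y in zip(xs, ys):
        if abs(x) >= effect_threshold and abs(y) >= effect_threshold:
            if x * y < 0:
                consistent += 1
            else:
                inconsistent += 1

    return {
        "n_genes": len(shared),
        "expression_lfc_by_silencing_category": {
            c: {"n": len(v), "median": float(np.median(v))} for c, v in by_cat.items()
        },
        "category_rank_sum_p": cat_tests,
        "de_status_crosstab": {
            de_cat: dict(row) for de_cat, row in sorted(crosstab.items())
        },
        "crosstab_chi2_p": chi_p,
        "pearson_r": r,
        "permutation_p": perm_p,
        "sign_consistent": consistent,
        "sign_inconsistent": inconsistent,
    }


def te_type_rpkm(
    type_read_counts: Mapping[str, Mapping[str, float]],
    type_lengths: Mapping[str, Mapping[str, float]],
    total_exonic_reads: Mapping[str, float],
) -> pd.DataFrame:
    """RPKM per TE type per species over the agglomerated genomic copies.

    ``RPKM = reads * 1e9 / (agglomerated_length * total_exonic_reads)``; a
    type is flagged expressed iff RPKM is strictly greater than 1.
    """
    rows = []
    for sp, reads in type_read_counts.items():
        total = total_exonic_reads[sp]
        if total <= 0:
            raise ValueError(f"non-positive total exonic reads for species {sp}")
        for te_type, r in reads.items():
            length = type_lengths[sp][te_type]
            if length <= 0:
                raise ValueError(f"non-positive agglomerated length for {te_type}")
            rpkm = r * 1e9 / (length * total)
            rows.append(
                {
                    "species": sp,
                    "te_type": te_type,
                    "reads": r,
                    "length": length,
                    "rpkm": rpkm,
                    "expressed": rpkm > 1.0,
                }
            )
    return pd.DataFrame(rows)


def gene_set_h3k9me3_overlap(
    gene_set: Sequence[str],
    genes: Sequence[GeneModel],
    regions: Sequence[OrthologousRegion],
    diff: Mapping[str, DifferentialResult],
    mode: str = "body_half",
) -> tuple[pd.DataFrame, list[str]]:
    """Overlap a curated gene set (e.g. KRAB-ZNF genes) with H3K9me3 regions.

    ``body_half`` requires >= 50% of the gene span covered by regions;
    ``tss_1kb_half`` requires >= 50% of the 1 kb interval centred on the TSS.
    Overlapping genes inherit the category of the largest-overlap region.
    Returns (per-gene table, unknown gene ids).
    """
    if mode not in ("body_half", "tss_1kb_half"):
        raise ValueError(f"unknown mode {mode!r}")
    by_id = {g.gene_id: g for g in genes}
    unknown = [g for g in gene_set if g not in by_id]
    cover = IntervalCoverage([r.interval_a for r in regions])
    spans = sorted(
        ((r.interval_a, r.region_id) for r in regions),
        key=lambda t: (t[0].chrom, t[0].start),
    )
    rows = []
    for gid in gene_set:
        gene = by_id.get(gid)
        if gene is None:
            continue
        if mode == "body_half":
            iv = gene.span
        else:
            iv = GenomicInterval(gene.chrom, max(0, gene.tss - 500), gene.tss + 500)
        frac = cover.fraction(iv)
        overlapping = frac >= 0.5
        category = None
        if overlapping:
            best = None
            for span, rid in spans:
                ov = iv.overlap_len(span)
                if ov > 0:
                    key = (-ov, rid)
                    if best is None or key < best:
                        best = key
            if best is not None:
                res = diff.get(best[1])
                category = res.category if res is not None else "shared"
        rows.append(
            {
                "gene_id": gid,
                "coverage": frac,
                "overlapping": overlapping,
                "category": category,
            }
        )
    return pd.DataFrame(rows), unknown


def nonorthologous_te_association(
    per_species_tes: Mapping[str, Sequence[TEInstance]],
    per_species_peaks: Mapping[str, Sequence[GenomicInterval]],
    genes: Sequence[GeneModel],
    window_sizes: Sequence[int],
    gene_de: Mapping[str, DifferentialResult],
    chain_ab: Sequence[ChainAlignment],
    chain_ba: Sequence[ChainAlignment],
    chrom_sizes: Mapping[str, Mapping[str, int]],
    min_frac: float = 0.5,
    min_match: float = 0.7,
) -> pd.DataFrame:
    """Associate silencing of non-orthologous TEs with expression divergence.

    Genome-A gene TSSs are used directly for species A and lifted (with
    their 1 kb context, reciprocally) to genome B for species B. Per species
    and window size, genes whose upstream window holds at least one
    non-orthologous TE are labelled ``silent`` when every such TE overlaps
    that species' peaks by >= ``min_frac`` of its length, else
    ``non_silent``; |expression log2fc| is compared between labels by
    rank-sum.
    """
    lifted_tss: dict[str, tuple[str, int]] = {}
    for gene in genes:
        context = GenomicInterval(
            gene.chrom, max(0, gene.tss - 500), gene.tss + 500
        )
        res = reciprocal_lift(context, chain_ab, chain_ba, min_match)
        if isinstance(res, LiftFailure):
            continue
        point = lift_interval(
            GenomicInterval(gene.chrom, gene.tss, gene.tss + 1), chain_ab, min_match
        )
        if point is None:
            continue
        lifted_tss[gene.gene_id] = (point.chrom, point.start)

    rows = []
    for sp in sorted(per_species_tes):
        cover = IntervalCoverage(per_species_peaks[sp])
        te_by_chrom: dict[str, list[TEInstance]] = defaultdict(list)
        for te in per_species_tes[sp]:
            te_by_chrom[te.interval.chrom].append(te)
        for size in window_sizes:
            silent, non_silent = [], []
            n_tss_failed = 0
            for gene in genes:
                if gene.gene_id not in gene_de:
                    continue
                if sp == "A":
                    chrom, tss = gene.chrom, gene.tss
                else:
                    if gene.gene_id not in lifted_tss:
                        n_tss_failed += 1
                        continue
                    chrom, tss = lifted_tss[gene.gene_id]
                clen = chrom_sizes[sp].get(chrom)
                if clen is None or not (0 <= tss < clen):
                    continue
                win = upstream_window(tss, gene.strand, size, clen, chrom)
                if win is None:
                    continue
                tes = [
                    te
                    for te in te_by_chrom.get(chrom, [])
                    if te.interval.start < win.end and te.interval.end > win.start
                ]
                if not tes:
                    continue
                lfc = gene_de[gene.gene_id].log2fc
                if not np.isfinite(lfc):
                    continue
                if all(cover.fraction(te.interval) >= min_frac for te in tes):
                    silent.append(abs(lfc))
                else:
                    non_silent.append(abs(lfc))
            p = float("nan")
            if len(silent) >= 2 and len(non_silent) >= 2:
                _, p = rank_sum_test(silent, non_silent)
            rows.append(
                {
                    "species": sp,
                    "window": size,
                    "n_silent": len(silent),
                    "n_non_silent": len(non_silent),
                    "n_tss_unlifted": n_tss_failed,
                    "median_abs_lfc_silent": float(np.median(silent)) if silent else float("nan"),
                    "median_abs_lfc_non_silent": float(np.median(non_silent)) if non_silent else float("nan"),
                    "rank_sum_p": p,
                }
            )
    return pd.DataFrame(rows)
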