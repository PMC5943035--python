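"""Plain-text readers/writers for every artifact the pipeline exchanges.

Formats: FASTA (genomes, via Biopython), UCSC chain, BED3 (fragments),
BED6+ (peaks/regions), the 8-column TE TSV, gene table TSV, count matrix
TSV with a species sidecar, and ground-truth TSVs.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GenomicInterval
from .genes import GeneModel
from .peaks import CountMatrix, OrthologousRegion, Peak

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed3",
    "write_bed3",
    "write_peaks",
    "write_regions",
    "write_count_matrix",
    "read_count_matrix",
    "read_gene_table",
    "write_gene_table",
    "write_cohort",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed3(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, *_ = line.split("\t")
            out.append(GenomicInterval(chrom, int(start), int(end)))
    return out


def write_bed3(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_peaks(peaks: Sequence[Peak], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak{i}\t"
                f"{p.enrichment:.4g}\t.\t{p.qvalue:.4g}\n"
            )


def write_regions(regions: Sequence[OrthologousRegion], path) -> None:
    """BED6+ with both species' coordinates and mappabilities."""
    with open(path, "w") as fh:
        fh.write(
            "#chromA\tstartA\tendA\tregion_id\tscore\tstrand\t"
            "chromB\tstartB\tendB\tmean_map_A\tmean_map_B\n"
        )
        for r in regions:
            a, b = r.interval_a, r.interval_b
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{r.region_id}\t0\t.\t"
                f"{b.chrom}\t{b.start}\t{b.end}\t{r.mean_map_a:.4f}\t{r.mean_map_b:.4f}\n"
            )


def write_count_matrix(matrix: CountMatrix, path, species_path=None) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="feature")
    if species_path is not None:
        pd.Series(matrix.species, name="species").to_csv(
            species_path, sep="\t", index_label="individual"
        )


def read_count_matrix(path, species_path) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    species = pd.read_csv(species_path, sep="\t", index_col=0)["species"].to_dict()
    return CountMatrix(counts=counts, species=species)


def read_gene_table(path) -> list[GeneModel]:
    """TSV: gene, chrom, txStart, txEnd, strand (one row per transcript)."""
    df = pd.read_csv(path, sep="\t")
    genes = []
    for gid, sub in df.groupby("gene", sort=True):
        strands = sub["strand"].unique()
        if len(strands) != 1:
            raise ValueError(f"gene {gid} has inconsistent strands")
        transcripts = list(zip(sub["txStart"].astype(int), sub["txEnd"].astype(int)))
        genes.append(
            GeneModel(str(gid), str(sub["chrom"].iloc[0]), str(strands[0]), transcripts)
        )
    return genes


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    rows = []
    for g in genes:
        for s, e in g.transcripts:
            rows.append(
                {"gene": g.gene_id, "chrom": g.chrom, "txStart": s, "txEnd": e,
                 "strand": g.strand}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_cohort(cohort, outdir) -> None:
    """Write every simulated artifact of a cohort as plain text."""
    from .chainmap import write_chain
    from .repeats import write_repeatmasker_table

    os.makedirs(outdir, exist_ok=True)
    join = lambda *p: os.path.join(outdir, *p)
    write_fasta(cohort.pair.genome_a, join("genomeA.fa"))
    write_fasta(cohort.pair.genome_b, join("genomeB.fa"))
    write_chain(cohort.pair.chains_ab, join("A_to_B.chain"))
    write_chain(cohort.pair.chains_ba, join("B_to_A.chain"))
    write_repeatmasker_table(cohort.rmsk_a, join("rmskA.tsv"))
    write_repeatmasker_table(cohort.rmsk_b, join("rmskB.tsv"))
    os.makedirs(join("fragments"), exist_ok=True)
    for (indiv, assay), frags in sorted(cohort.fragments.items()):
        write_bed3(frags, join("fragments", f"{indiv}_{assay}.bed"))
    write_gene_table(cohort.genes, join("genes.tsv"))
    cohort.gene_counts.to_csv(join("gene_counts.tsv"), sep="\t", index_label="gene")
    cohort.te_type_reads.to_csv(join("te_type_reads.tsv"), sep="\t", index=False)
    pd.Series(cohort.total_exonic_reads, name="total_exonic_reads").to_csv(
        join("total_exonic_reads.tsv"), sep="\t", index_label="species"
    )
    truth_rows = []
    for uid, t in sorted(cohort.truth.te_by_uid.items()):
        truth_rows.append(
            {
                "uid": uid,
                "te_class": t.te_class,
                "family": t.family,
                "name": t.name,
                "silencing": t.silencing,
                "orthology": t.orthology,
                "te_id_A": t.te_a.te_id if t.te_a else "",
                "te_id_B": t.te_b.te_id if t.te_b else "",
            }
        )
    pd.DataFrame(truth_rows).to_csv(join("truth_te.tsv"), sep="\t", index=False)
    pd.Series(cohort.truth.gene_effect, name="true_log2fc").sort_index().to_csv(
        join("truth_genes.tsv"), sep="\t", index_label="gene"
    )
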