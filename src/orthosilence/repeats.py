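"""Transposable-element annotation handling and cross-species TE orthology.

TE instances come from RepeatMasker-style tables carrying the type/family/
class hierarchy and the milliDiv consensus divergence (substitutions per
1,000 bp between an instance and its family consensus).

Orthologous TE calling is a four-step reciprocal procedure between the two
species' annotation tables: lift species-A instances to B, keep those
landing on an identically named B instance with sufficient base overlap,
lift back to A; repeat seeded from B; intersect the two resulting sets in A
coordinates.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .chainmap import ChainAlignment, lift_interval
from .core import GenomicInterval

__all__ = [
    "TE_CLASSES",
    "TEInstance",
    "OrthologousTE",
    "parse_repeatmasker_table",
    "write_repeatmasker_table",
    "orthologous_te_set",
    "partition_te_sets",
]

TE_CLASSES = ("LINE", "SINE", "LTR", "DNA", "SVA")


@dataclass(frozen=True)
class TEInstance:
    """One annotated repeat occurrence."""

    interval: GenomicInterval
    name: str
    family: str
    te_class: str
    milli_div: float
    species: str = ""

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown TE class {self.te_class!r}")
        if not (0 <= self.milli_div <= 1000):
            raise ValueError(f"milliDiv {self.milli_div} outside [0, 1000]")

    @property
    def te_id(self) -> str:
        return f"{self.species}:{self.interval.chrom}:{self.interval.start}-{self.interval.end}:{self.name}"


@dataclass(frozen=True)
class OrthologousTE:
    """A TE with reciprocally corresponding coordinates in both genomes and a
    shared type name. Length and milliDiv are read from the A instance."""

    te_a: TEInstance
    te_b: TEInstance

    def __post_init__(self) -> None:
        if self.te_a.name != self.te_b.name:
            raise ValueError("orthologous TE pair must share a name")

    @property
    def name(self) -> str:
        return self.te_a.name


def parse_repeatmasker_table(path, species: str = "") -> list[TEInstance]:
    """Read the 8-column TE TSV: chrom, start, end, name, milliDiv, strand,
    family, class (coordinates 0-based half-open)."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise ValueError(f"{path}:{lineno}: expected 8 columns, got {len(parts)}")
            chrom, start, end, name, mdiv, strand, family, te_class = parts
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
                te = TEInstance(iv, name, family, te_class, float(mdiv), species)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append(te)
    return out


def write_repeatmasker_table(tes: Sequence[TEInstance], path) -> None:
    with open(path, "w") as fh:
        for te in tes:
            iv = te.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{te.name}\t{te.milli_div:g}\t"
                f"{iv.strand}\t{te.family}\t{te.te_class}\n"
            )


def _index_by_chrom(tes: Sequence[TEInstance]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, te in enumerate(tes):
        trees[te.interval.chrom].addi(te.interval.start, te.interval.end, i)
    return dict(trees)


def _best_same_name_hit(
    span: GenomicInterval,
    tes: Sequence[TEInstance],
    trees: dict[str, IntervalTree],
    name: str,
    min_bp_overlap: float,
) -> int | None:
    """Index of the same-name instance overlapping ``span`` by at least
    ``min_bp_overlap`` of the span; ties by largest overlap then smallest
    start."""
    tree = trees.get(span.chrom)
    if tree is None:
        return None
    best: tuple[int, int, int] | None = None  # (-overlap, start, index)
    for hit in tree.overlap(span.start, span.end):
        te = tes[hit.data]
        if te.name != name:
            continue
        ov = span.overlap_len(te.interval)
        if ov / span.length < min_bp_overlap:
            continue
        key = (-ov, te.interval.start, hit.data)
        if best is None or key < best:
            best = key
    return None if best is None else best[2]


def _one_direction(
    src_tes: Sequence[TEInstance],
    dst_tes: Sequence[TEInstance],
    dst_trees: dict[str, IntervalTree],
    chain_fwd: Sequence[ChainAlignment],
    chain_rev: Sequence[ChainAlignment],
    min_match: float,
    min_bp_overlap: float,
    log: dict[str, int],
) -> list[tuple[int, int, GenomicInterval]]:
    """Stages 1-3 seeded from ``src_tes``: lift, same-name overlap match in
    the other table, lift back. Returns (src index, dst index, back-lifted
    source-genome span)."""
    out = []
    for i, te in enumerate(src_tes):
        lifted = lift_interval(te.interval, chain_fwd, min_match)
        if lifted is None:
            log["stage1_unliftable"] += 1
            continue
        j = _best_same_name_hit(lifted, dst_tes, dst_trees, te.name, min_bp_overlap)
        if j is None:
            log["stage2_no_name_match"] += 1
            continue
        back = lift_interval(lifted, chain_rev, min_match)
        if back is None:
            log["stage3_unliftable_back"] += 1
            continue
        out.append((i, j, back))
    return out


def orthologous_te_set(
    rmsk_a: Sequence[TEInstance],
    rmsk_b: Sequence[TEInstance],
    chain_ab: Sequence[ChainAlignment],
    chain_ba: Sequence[ChainAlignment],
    min_match: float = 0.7,
    min_bp_overlap: float = 0.5,
) -> tuple[list[OrthologousTE], dict[str, int]]:
    """Reciprocal orthologous TE construction.

    (1) lift A instances to B at ``min_match``; (2) keep those overlapping an
    identically named B instance by >= ``min_bp_overlap`` of the lifted span;
    (3) lift back to A; (4) repeat seeded from B; (5) intersect the two
    resulting sets in A coordinates, requiring reciprocal overlap of at least
    ``min_bp_overlap`` of the shorter span between the A-seeded back-lifted
    span and the B-seeded matched A instance. Exclusions are tallied by stage.
    """
    log: dict[str, int] = defaultdict(int)
    trees_a = _index_by_chrom(rmsk_a)
    trees_b = _index_by_chrom(rmsk_b)

    from_a = _one_direction(
        rmsk_a, rmsk_b, trees_b, chain_ab, chain_ba, min_match, min_bp_overlap, log
    )
    from_b = _one_direction(
        rmsk_b, rmsk_a, trees_a, chain_ba, chain_ab, min_match, min_bp_overlap, log
    )

    # Stage 5: index the B-seeded set by its matched A instance.
    b_spans: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for b_idx, a_idx, _back_b in from_b:
        iv = rmsk_a[a_idx].interval
        b_spans[iv.chrom].addi(iv.start, iv.end, (a_idx, b_idx))

    pairs: dict[int, tuple[int, int]] = {}
    for a_idx, b_idx, back_span in from_a:
        tree = b_spans.get(back_span.chrom)
        if tree is None:
            log["stage5_no_intersection"] += 1
            continue
        best: tuple[int, int, tuple[int, int]] | None = None
        for hit in tree.overlap(back_span.start, back_span.end):
            other = GenomicInterval(back_span.chrom, hit.begin, hit.end)
            ov = back_span.overlap_len(other)
            shorter = min(back_span.length, other.length)
            if ov / shorter < min_bp_overlap:
                continue
            if rmsk_a[hit.data[0]].name != rmsk_a[a_idx].name:
                continue
            key = (-ov, hit.begin, hit.data)
            if best is None or key < best:
                best = key
        if best is None:
            log["stage5_no_intersection"] += 1
            continue
        pairs[a_idx] = (a_idx, b_idx)

    ortho = [
        OrthologousTE(te_a=rmsk_a[a], te_b=rmsk_b[b])
        for a, b in sorted(pairs.values())
    ]
    return ortho, dict(log)


def partition_te_sets(
    rmsk_a: Sequence[TEInstance],
    rmsk_b: Sequence[TEInstance],
    ortho: Sequence[OrthologousTE],
) -> dict[str, list]:
    """Split each species' annotations into orthologous, non-orthologous and
    species-specific (name absent from the other species' table) sets.

    Per species the orthologous and non-orthologous sets partition the full
    table; species-specific instances are the subset of non-orthologous ones
    whose type name never occurs in the other table.
    """
    ortho_a_ids = {o.te_a.te_id for o in ortho}
    ortho_b_ids = {o.te_b.te_id for o in ortho}
    names_a = {te.name for te in rmsk_a}
    names_b = {te.name for te in rmsk_b}

    non_a = [te for te in rmsk_a if te.te_id not in ortho_a_ids]
    non_b = [te for te in rmsk_b if te.te_id not in ortho_b_ids]
    return {
        "orthologous": list(ortho),
        "non_orthologous_A": non_a,
        "non_orthologous_B": non_b,
        "species_specific_A": [te for te in non_a if te.name not in names_b],
        "species_specific_B": [te for te in non_b if te.name not in names_a],
    }
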