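"""Pairwise-genome coordinate mapping and mappability.

Implements the UCSC chain format (parser/writer), liftOver-style interval
mapping with a minimum-match fraction, reciprocal-and-unique lifting, and
exact k-mer mappability tracks.

Semantics follow the classic ``liftOver -minMatch`` contract: an interval
maps if at least ``min_match`` of its bases fall inside aligned blocks of the
single best-scoring chain covering it, and the output is the envelope of the
mapped bases on the target genome's plus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import GenomicInterval

__all__ = [
    "ChainAlignment",
    "ChainParseError",
    "parse_chain",
    "write_chain",
    "lift_interval",
    "reciprocal_lift",
    "LiftFailure",
    "MappabilityTrack",
    "kmer_mappability",
    "mean_mappability",
    "write_bedgraph",
]


class ChainParseError(ValueError):
    """Malformed chain file; message names the offending line."""


@dataclass
class ChainAlignment:
    """One gapped pairwise alignment in UCSC chain terms.

    ``src`` is the genome intervals are lifted *from* (the chain file's
    "target"/``t`` side in UCSC nomenclature), ``tgt`` the genome they are
    lifted *to* (UCSC "query"/``q``). ``blocks`` is an ordered list of
    ``(size, dsrc, dtgt)`` triples: ``size`` aligned bases followed by gaps of
    ``dsrc``/``dtgt`` bases on either side; the final block has zero gaps.
    """

    score: float
    src_chrom: str
    src_size: int
    src_strand: str
    src_start: int
    src_end: int
    tgt_chrom: str
    tgt_size: int
    tgt_strand: str
    tgt_start: int
    tgt_end: int
    blocks: list[tuple[int, int, int]] = field(default_factory=list)
    chain_id: int = 0

    def validate(self) -> None:
        if any(size <= 0 for size, _, _ in self.blocks):
            raise ChainParseError(f"chain {self.chain_id}: non-positive block size")
        src_span = sum(s + ds for s, ds, _ in self.blocks)
        tgt_span = sum(s + dt for s, _, dt in self.blocks)
        if src_span != self.src_end - self.src_start:
            raise ChainParseError(
                f"chain {self.chain_id}: block sums ({src_span}) != declared "
                f"source span ({self.src_end - self.src_start})"
            )
        if tgt_span != self.tgt_end - self.tgt_start:
            raise ChainParseError(
                f"chain {self.chain_id}: block sums ({tgt_span}) != declared "
                f"target span ({self.tgt_end - self.tgt_start})"
            )

    def invert(self) -> "ChainAlignment":
        """Swap source and target roles (exact inversion).

        Only plus/plus chains are invertible here; the simulator and all
        in-package chains are plus/plus.
        """
        if self.src_strand != "+" or self.tgt_strand != "+":
            raise NotImplementedError("only +/+ chains can be inverted")
        return ChainAlignment(
            score=self.score,
            src_chrom=self.tgt_chrom,
            src_size=self.tgt_size,
            src_strand="+",
            src_start=self.tgt_start,
            src_end=self.tgt_end,
            tgt_chrom=self.src_chrom,
            tgt_size=self.src_size,
            tgt_strand="+",
            tgt_start=self.src_start,
            tgt_end=self.src_end,
            blocks=[(s, dt, ds) for s, ds, dt in self.blocks],
            chain_id=self.chain_id,
        )

    def aligned_pairs(self) -> Iterable[tuple[int, int, int]]:
        """Yield ``(src_start, tgt_start, size)`` per aligned block, with
        target positions in target *strand* coordinates."""
        s, t = self.src_start, self.tgt_start
        for size, dsrc, dtgt in self.blocks:
            yield s, t, size
            s += size + dsrc
            t += size + dtgt


def parse_chain(path) -> list[ChainAlignment]:
    """Read a UCSC chain file, validating block arithmetic per chain."""
    chains: list[ChainAlignment] = []
    current: ChainAlignment | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                parts = line.split()
                if len(parts) != 13:
                    raise ChainParseError(f"line {lineno}: malformed chain header")
                try:
                    current = ChainAlignment(
                        score=float(parts[1]),
                        src_chrom=parts[2],
                        src_size=int(parts[3]),
                        src_strand=parts[4],
                        src_start=int(parts[5]),
                        src_end=int(parts[6]),
                        tgt_chrom=parts[7],
                        tgt_size=int(parts[8]),
                        tgt_strand=parts[9],
                        tgt_start=int(parts[10]),
                        tgt_end=int(parts[11]),
                        chain_id=int(parts[12]),
                    )
                except ValueError as exc:
                    raise ChainParseError(f"line {lineno}: {exc}") from exc
                chains.append(current)
            else:
                if current is None:
                    raise ChainParseError(f"line {lineno}: block before chain header")
                parts = line.split()
                try:
                    if len(parts) == 3:
                        current.blocks.append(
                            (int(parts[0]), int(parts[1]), int(parts[2]))
                        )
                    elif len(parts) == 1:
                        current.blocks.append((int(parts[0]), 0, 0))
                    else:
                        raise ValueError("expected 1 or 3 fields")
                except ValueError as exc:
                    raise ChainParseError(f"line {lineno}: {exc}") from exc
    for chain in chains:
        chain.validate()
    return chains


def write_chain(chains: Sequence[ChainAlignment], path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            score = int(c.score) if float(c.score).is_integer() else c.score
            fh.write(
                f"chain {score} {c.src_chrom} {c.src_size} {c.src_strand} "
                f"{c.src_start} {c.src_end} {c.tgt_chrom} {c.tgt_size} "
                f"{c.tgt_strand} {c.tgt_start} {c.tgt_end} {c.chain_id}\n"
            )
            for i, (size, ds, dt) in enumerate(c.blocks):
                if i == len(c.blocks) - 1:
                    fh.write(f"{size}\n")
                else:
                    fh.write(f"{size} {ds} {dt}\n")
            fh.write("\n")


@dataclass
class LiftFailure:
    """Reason an interval failed to lift; ``reason`` is one of
    ``no_chain``, ``low_match_fwd``, ``low_match_back``, ``nonreciprocal``."""

    reason: str


def _tgt_piece_to_plus(chain: ChainAlignment, lo: int, hi: int) -> tuple[int, int]:
    """Convert a target-strand-coordinate span to plus-strand coordinates."""
    if chain.tgt_strand == "+":
        return lo, hi
    return chain.tgt_size - hi, chain.tgt_size - lo


def _covered_bases(chain: ChainAlignment, iv: GenomicInterval) -> int:
    cov = 0
    for s0, _, size in chain.aligned_pairs():
        cov += max(0, min(iv.end, s0 + size) - max(iv.start, s0))
    return cov


def _map_envelope(chain: ChainAlignment, iv: GenomicInterval) -> GenomicInterval:
    lo = None
    hi = None
    for s0, t0, size in chain.aligned_pairs():
        a = max(iv.start, s0)
        b = min(iv.end, s0 + size)
        if a >= b:
            continue
        t_lo = t0 + (a - s0)
        t_hi = t0 + (b - s0)
        p_lo, p_hi = _tgt_piece_to_plus(chain, t_lo, t_hi)
        lo = p_lo if lo is None else min(lo, p_lo)
        hi = p_hi if hi is None else max(hi, p_hi)
    assert lo is not None and hi is not None
    return GenomicInterval(chain.tgt_chrom, lo, hi, iv.strand)


def _qualifying_chains(
    iv: GenomicInterval, chains: Sequence[ChainAlignment], min_match: float
) -> tuple[list[ChainAlignment], bool]:
    touched = False
    qualifying = []
    for chain in chains:
        if chain.src_chrom != iv.chrom:
            continue
        if chain.src_end <= iv.start or chain.src_start >= iv.end:
            continue
        touched = True
        if _covered_bases(chain, iv) / iv.length >= min_match:
            qualifying.append(chain)
    return qualifying, touched


def lift_interval(
    iv: GenomicInterval,
    chains: Sequence[ChainAlignment],
    min_match: float = 0.7,
) -> GenomicInterval | None:
    """Map ``iv`` to the target genome, or return ``None``.

    Succeeds iff >= ``min_match`` of the interval's bases lie inside aligned
    blocks of the best-scoring chain overlapping it. The result is the
    envelope of the mapped bases, reported on the target plus strand (the
    source strand is carried over as metadata).
    """
    if not (0 < min_match <= 1):
        raise ValueError("min_match must be in (0, 1]")
    qualifying, _ = _qualifying_chains(iv, chains, min_match)
    if not qualifying:
        return None
    best = max(qualifying, key=lambda c: c.score)
    return _map_envelope(best, iv)


def reciprocal_lift(
    iv: GenomicInterval,
    chain_fwd: Sequence[ChainAlignment],
    chain_rev: Sequence[ChainAlignment],
    min_match: float = 0.7,
) -> tuple[GenomicInterval, GenomicInterval] | LiftFailure:
    """Lift forward, lift the result back, and demand the round trip lands on
    the original locus.

    Returns ``(iv_source, iv_target)`` iff (i) exactly one forward chain
    reaches ``min_match`` coverage (uniqueness), (ii) the forward image lifts
    back under the same uniqueness rule, and (iii) the round-trip interval
    overlaps ``iv`` by at least ``min_match`` of its length. Failures return a
    :class:`LiftFailure` carrying a reason code.
    """
    fwd_q, touched = _qualifying_chains(iv, chain_fwd, min_match)
    if not fwd_q:
        return LiftFailure("no_chain" if not touched else "low_match_fwd")
    if len(fwd_q) > 1:
        return LiftFailure("nonreciprocal")
    lifted = _map_envelope(fwd_q[0], iv)

    back_q, _ = _qualifying_chains(lifted, chain_rev, min_match)
    if not back_q:
        return LiftFailure("low_match_back")
    if len(back_q) > 1:
        return LiftFailure("nonreciprocal")
    back = _map_envelope(back_q[0], lifted)

    if back.overlap_len(iv) / iv.length < min_match:
        return LiftFailure("nonreciprocal")
    return iv, lifted


# ---------------------------------------------------------------------------
# Mappability
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MappabilityTrack:
    """Per-base uniqueness scores: 1 / (exact genome-wide occurrences of the
    k-mer starting at each base, counting both strands).

    The trailing ``k-1`` bases of each chromosome inherit the score of the
    last full k-mer start.
    """

    k: int
    scores: dict[str, np.ndarray]


def kmer_mappability(genome: Mapping[str, str], k: int) -> MappabilityTrack:
    """Exact k-mer mappability for every base of ``genome``.

    ``genome`` maps chromosome name to sequence. Occurrences of a k-mer are
    counted at all forward positions plus all positions where its reverse
    complement occurs; a palindromic k-mer is not double-counted at its own
    site.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not genome:
        raise ValueError("empty genome")
    if all(len(seq) < k for seq in genome.values()):
        raise ValueError(f"k={k} exceeds every chromosome length")

    counts: dict[str, int] = {}
    for seq in genome.values():
        s = seq.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1

    scores: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        s = seq.upper()
        n = len(s)
        arr = np.ones(n, dtype=float)
        last = 1.0
        for i in range(n - k + 1):
            kmer = s[i : i + k]
            rc = _revcomp(kmer)
            occ = counts.get(kmer, 0)
            if rc != kmer:
                occ += counts.get(rc, 0)
            last = 1.0 / occ
            arr[i] = last
        arr[max(0, n - k + 1) :] = last
        scores[chrom] = arr
    return MappabilityTrack(k=k, scores=scores)


def mean_mappability(iv: GenomicInterval, track: MappabilityTrack) -> float:
    """Arithmetic mean of per-base mappability over ``[start, end)``."""
    if iv.chrom not in track.scores:
        raise KeyError(f"chromosome {iv.chrom} absent from mappability track")
    arr = track.scores[iv.chrom]
    if iv.start >= len(arr):
        raise ValueError(f"interval {iv} outside track bounds")
    window = arr[iv.start : min(iv.end, len(arr))]
    if window.size == 0:
        raise ValueError(f"interval {iv} has empty intersection with track")
    return float(window.mean())


def write_bedgraph(track: MappabilityTrack, path) -> None:
    """Write the track as bedGraph, run-length collapsing equal scores."""
    with open(path, "w") as fh:
        for chrom in sorted(track.scores):
            arr = track.scores[chrom]
            start = 0
            for i in range(1, len(arr) + 1):
                if i == len(arr) or arr[i] != arr[start]:
                    fh.write(f"{chrom}\t{start}\t{i}\t{arr[start]:.6g}\n")
                    start = i
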