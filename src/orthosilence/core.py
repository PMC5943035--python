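"""Core genomic-interval primitives.

All coordinates in this package are 0-based, half-open ``[start, end)`` on a
named chromosome — the BED convention. :class:`GenomicInterval` is the
universal currency passed between modules: ChIP fragments, peaks, orthologous
regions, TE instances and gene windows all carry one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

__all__ = ["GenomicInterval", "merge_intervals", "total_length"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span.

    Parameters
    ----------
    chrom : str
        Chromosome name; must be non-empty.
    start, end : int
        0-based inclusive start, exclusive end; ``0 <= start < end``.
    strand : str
        One of ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def with_coords(self, start: int, end: int) -> "GenomicInterval":
        return replace(self, start=start, end=end)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def merge_intervals(
    intervals: Iterable[GenomicInterval], *, book_ended: bool = True
) -> list[GenomicInterval]:
    """Union-merge intervals; overlapping (and, by default, book-ended,
    i.e. ``a.end == b.start``) intervals are fused into one span.

    The result is sorted and deterministic regardless of input order; strand
    information is dropped (merged spans are unstranded).
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom:
            prev = merged[-1]
            joined = iv.start <= prev.end if book_ended else iv.start < prev.end
            if joined:
                if iv.end > prev.end:
                    merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
                continue
        merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def total_length(intervals: Sequence[GenomicInterval]) -> int:
    """Total bases covered by an already-merged (disjoint) interval set."""
    return sum(iv.length for iv in intervals)


class IntervalCoverage:
    """Fast covered-base queries against the union of an interval set.

    Builds per-chromosome sorted, merged spans once; ``covered(iv)`` then
    returns how many bases of ``iv`` fall inside the union in O(log n).
    """

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        import numpy as np

        self._np = np
        self._starts: dict[str, "np.ndarray"] = {}
        self._ends: dict[str, "np.ndarray"] = {}
        merged = merge_intervals(intervals, book_ended=False)
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            self._starts[chrom] = np.array([iv.start for iv in ivs])
            self._ends[chrom] = np.array([iv.end for iv in ivs])

    def covered(self, iv: GenomicInterval) -> int:
        np = self._np
        starts = self._starts.get(iv.chrom)
        if starts is None:
            return 0
        ends = self._ends[iv.chrom]
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        cov = 0
        for k in range(lo, hi):
            cov += max(0, min(iv.end, int(ends[k])) - max(iv.start, int(starts[k])))
        return cov

    def fraction(self, iv: GenomicInterval) -> float:
        return self.covered(iv) / iv.length
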