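"""Broad-domain ChIP enrichment calling and orthologous region construction.

The caller is a windowed Poisson scan tuned for broad heterochromatic domains
(H3K9me3-like signal): the genome is tiled in fixed windows, each window's
ChIP fragment count is tested against a local expectation taken from the
depth-scaled Input (floored at the genome-wide ChIP mean), p-values are
BH-adjusted across windows, and significant windows separated by at most
``gap`` bases are merged into domains.

Domains called per individual are then made cross-species comparable: each
peak must map reciprocally and uniquely between the genomes, surviving peaks
from all individuals of both species are union-merged in genome-A
coordinates, merged regions are lifted once to genome B, and regions with
mean 50-mer mappability <= ``min_map`` in either genome are dropped.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .chainmap import (
    ChainAlignment,
    LiftFailure,
    MappabilityTrack,
    lift_interval,
    mean_mappability,
    reciprocal_lift,
)
from .core import GenomicInterval, merge_intervals
from .stats import bh_adjust

__all__ = [
    "Peak",
    "OrthologousRegion",
    "CountMatrix",
    "call_broad_peaks",
    "build_orthologous_regions",
    "count_fragments_in_regions",
    "filter_regions_by_occupancy",
]


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    enrichment: float
    qvalue: float


@dataclass
class OrthologousRegion:
    """An H3K9me3 region with coordinates in both genomes."""

    region_id: str
    interval_a: GenomicInterval
    interval_b: GenomicInterval
    mean_map_a: float
    mean_map_b: float
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class CountMatrix:
    """Features x individuals integer counts plus a species label per column."""

    counts: pd.DataFrame
    species: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.species)
        if missing:
            raise ValueError(f"individuals without species label: {sorted(missing)}")


def _window_counts(
    fragments: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    window: int,
) -> dict[str, np.ndarray]:
    """Fragment-midpoint counts per tiling window."""
    out = {}
    mids = defaultdict(list)
    for frag in fragments:
        mids[frag.chrom].append((frag.start + frag.end) // 2)
    for chrom, size in chrom_sizes.items():
        n_win = (size + window - 1) // window
        m = np.asarray(mids.get(chrom, []), dtype=int)
        if m.size:
            out[chrom] = np.bincount(
                np.clip(m // window, 0, n_win - 1), minlength=n_win
            ).astype(float)
        else:
            out[chrom] = np.zeros(n_win)
    return out


def call_broad_peaks(
    chip: Sequence[GenomicInterval],
    input_frags: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    window: int = 1000,
    gap: int = 3000,
    q_max: float = 0.1,
) -> list[Peak]:
    """Call broad enrichment domains from ChIP vs Input fragments.

    Per window, the expected count is
    ``max(depth-scaled Input count, genome-wide ChIP mean per window)``;
    the upper-tail Poisson p-value of the ChIP count is BH-adjusted across
    all windows, and windows at ``q <= q_max`` within ``gap`` bases of each
    other merge into a single domain reported with the minimum q.
    """
    if not chip or not input_frags:
        raise ValueError("ChIP and Input fragment sets must both be nonempty")
    if window < 1:
        raise ValueError("window must be >= 1")

    chip_w = _window_counts(chip, chrom_sizes, window)
    inp_w = _window_counts(input_frags, chrom_sizes, window)
    depth_ratio = len(chip) / len(input_frags)
    n_windows = sum(arr.size for arr in chip_w.values())
    chip_mean = len(chip) / n_windows

    chroms, starts, obs, lam = [], [], [], []
    for chrom in chrom_sizes:
        c = chip_w[chrom]
        i = inp_w[chrom]
        expected = np.maximum(i * depth_ratio, chip_mean)
        for w_idx in range(c.size):
            chroms.append(chrom)
            starts.append(w_idx * window)
            obs.append(c[w_idx])
            lam.append(expected[w_idx])
    obs_arr = np.asarray(obs)
    lam_arr = np.asarray(lam)
    pvals = stats.poisson.sf(obs_arr - 1, lam_arr)
    qvals = bh_adjust(pvals)

    sig = qvals <= q_max
    peaks: list[Peak] = []
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for idx in np.flatnonzero(sig):
        by_chrom[chroms[idx]].append(idx)
    for chrom, idxs in by_chrom.items():
        idxs.sort(key=lambda i: starts[i])
        run: list[int] = []
        for idx in idxs + [None]:  # type: ignore[list-item]
            if run and (
                idx is None or starts[idx] - (starts[run[-1]] + window) > gap
            ):
                s = starts[run[0]]
                e = min(starts[run[-1]] + window, chrom_sizes[chrom])
                q = float(min(qvals[i] for i in run))
                enr = float(np.mean([obs_arr[i] / lam_arr[i] for i in run]))
                peaks.append(Peak(GenomicInterval(chrom, s, e), enr, q))
                run = []
            if idx is not None:
                run.append(idx)
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


def build_orthologous_regions(
    peaks_by_individual: Mapping[str, Sequence[Peak]],
    species: Mapping[str, str],
    chain_ab: Sequence[ChainAlignment],
    chain_ba: Sequence[ChainAlignment],
    track_a: MappabilityTrack,
    track_b: MappabilityTrack,
    min_match: float = 0.7,
    min_map: float = 0.8,
) -> tuple[list[OrthologousRegion], dict[str, int]]:
    """Union-merge reciprocally liftable peaks from all individuals into one
    orthologous region set in genome-A coordinates.

    Individuals labelled species ``"A"`` carry peaks in genome-A coordinates
    (checked via A->B reciprocal lifting); species ``"B"`` peaks are lifted
    B->A. Merged regions are lifted once to genome B and filtered to mean
    mappability > ``min_map`` in both genomes. Returns the regions plus a
    tally of exclusion reasons.
    """
    log: dict[str, int] = defaultdict(int)
    a_coords: list[GenomicInterval] = []
    for indiv, peaks in peaks_by_individual.items():
        sp = species[indiv]
        for peak in peaks:
            if sp == "A":
                res = reciprocal_lift(peak.interval, chain_ab, chain_ba, min_match)
                if isinstance(res, LiftFailure):
                    log[f"peak_{res.reason}"] += 1
                    continue
                a_coords.append(res[0])
            else:
                res = reciprocal_lift(peak.interval, chain_ba, chain_ab, min_match)
                if isinstance(res, LiftFailure):
                    log[f"peak_{res.reason}"] += 1
                    continue
                a_coords.append(res[1])

    merged = merge_intervals(a_coords)
    regions: list[OrthologousRegion] = []
    for iv in merged:
        iv_b = lift_interval(iv, chain_ab, min_match)
        if iv_b is None:
            log["region_unliftable"] += 1
            continue
        map_a = mean_mappability(iv, track_a)
        map_b = mean_mappability(iv_b, track_b)
        if map_a <= min_map or map_b <= min_map:
            log["region_low_mappability"] += 1
            continue
        regions.append(
            OrthologousRegion(
                region_id=f"R{len(regions):06d}",
                interval_a=iv,
                interval_b=iv_b,
                mean_map_a=map_a,
                mean_map_b=map_b,
            )
        )
    return regions, dict(log)


def count_fragments_in_regions(
    regions: Sequence[OrthologousRegion],
    fragments_by_individual: Mapping[str, Sequence[GenomicInterval]],
    species: Mapping[str, str],
) -> CountMatrix:
    """Count fragments overlapping each region by >= 1 bp.

    Species-A individuals are counted against ``interval_a``, species-B
    against ``interval_b``; a fragment increments a region at most once but
    may hit several adjacent regions.
    """
    trees: dict[str, dict[str, IntervalTree]] = {"A": {}, "B": {}}
    for idx, region in enumerate(regions):
        for side, iv in (("A", region.interval_a), ("B", region.interval_b)):
            trees[side].setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, idx
            )

    data = {}
    for indiv, frags in fragments_by_individual.items():
        side = "A" if species[indiv] == "A" else "B"
        col = np.zeros(len(regions), dtype=int)
        chrom_trees = trees[side]
        for frag in frags:
            tree = chrom_trees.get(frag.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(frag.start, frag.end):
                col[hit.data] += 1
        data[indiv] = col
    counts = pd.DataFrame(
        data, index=[r.region_id for r in regions], columns=list(fragments_by_individual)
    )
    for region, row in zip(regions, counts.itertuples(index=False)):
        region.counts = dict(zip(counts.columns, row))
    return CountMatrix(counts=counts, species=dict(species))


def filter_regions_by_occupancy(matrix: CountMatrix) -> CountMatrix:
    """Keep features with nonzero counts in strictly more than half of all
    individuals (with 17 individuals: more than 8)."""
    if matrix.counts.empty:
        raise ValueError("empty count matrix")
    n = matrix.counts.shape[1]
    keep = (matrix.counts > 0).sum(axis=1) > n / 2
    return CountMatrix(counts=matrix.counts.loc[keep], species=matrix.species)
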