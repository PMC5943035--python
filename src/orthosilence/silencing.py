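"""TE-level silencing classification and property analyses.

A TE counts as H3K9me3-marked ("overlapping") when at least half of its
length is covered by the union of orthologous H3K9me3 regions; it then
inherits the differential-enrichment category of the single region with the
largest base overlap. The remaining operations reproduce the downstream
comparisons: within-species overlap by orthology category, per-class
enrichment, the length-matched control, property contrasts (length,
consensus divergence, TSS distance) and the copy-number association.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, IntervalCoverage
from .peaks import OrthologousRegion
from .repeats import OrthologousTE, TEInstance
from .stats import (
    DifferentialResult,
    bh_adjust,
    chi_squared_test,
    pearson_corr_permutation,
    rank_sum_test,
)

__all__ = [
    "SilencedTECall",
    "classify_te_silencing",
    "class_overlap_by_orthology",
    "enrichment_by_class",
    "length_matched_control",
    "property_compare",
    "annotate_overlap",
    "copy_number_vs_overlap",
]


@dataclass
class SilencedTECall:
    """Silencing status of one (orthologous) TE.

    ``status`` is ``non_overlapping`` when less than ``min_frac`` of the TE's
    length is covered by orthologous H3K9me3 regions, otherwise the category
    of the assigned (largest-overlap) region: ``shared`` / ``A_enriched`` /
    ``B_enriched``. ``log2fc`` is the assigned region's species effect.
    """

    te: OrthologousTE | TEInstance
    overlap_fraction: float
    status: str
    assigned_region: str | None = None
    log2fc: float = float("nan")

    @property
    def interval(self) -> GenomicInterval:
        te = self.te
        return te.te_a.interval if isinstance(te, OrthologousTE) else te.interval

    @property
    def te_class(self) -> str:
        te = self.te
        return te.te_a.te_class if isinstance(te, OrthologousTE) else te.te_class

    @property
    def family(self) -> str:
        te = self.te
        return te.te_a.family if isinstance(te, OrthologousTE) else te.family

    @property
    def milli_div(self) -> float:
        te = self.te
        return te.te_a.milli_div if isinstance(te, OrthologousTE) else te.milli_div


def classify_te_silencing(
    tes: Sequence[OrthologousTE | TEInstance],
    regions: Sequence[OrthologousRegion],
    diff: Mapping[str, DifferentialResult],
    min_frac: float = 0.5,
) -> list[SilencedTECall]:
    """Assign each TE a silencing category from region overlap in genome-A
    coordinates.

    ``diff`` maps region id to its differential result (category and
    log2fc). Overlap fraction is computed against the union of all region
    intervals; the category comes from the single region with the largest
    base overlap (ties broken by smaller region id).
    """
    cover = IntervalCoverage([r.interval_a for r in regions])
    trees: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    for r in regions:
        trees[r.interval_a.chrom].append((r.interval_a.start, r.interval_a.end, r.region_id))
    for spans in trees.values():
        spans.sort()

    calls = []
    for te in tes:
        iv = te.te_a.interval if isinstance(te, OrthologousTE) else te.interval
        frac = cover.fraction(iv)
        if frac >= min_frac:
            best: tuple[int, str] | None = None
            for start, end, rid in trees.get(iv.chrom, []):
                if start >= iv.end:
                    break
                ov = min(iv.end, end) - max(iv.start, start)
                if ov <= 0:
                    continue
                key = (-ov, rid)
                if best is None or key < best:
                    best = key
            assert best is not None
            rid = best[1]
            res = diff.get(rid)
            status = res.category if res is not None else "shared"
            log2fc = res.log2fc if res is not None else float("nan")
            calls.append(SilencedTECall(te, frac, status, rid, log2fc))
        else:
            calls.append(SilencedTECall(te, frac, "non_overlapping"))
    return calls


def _overlap_proportion(
    tes: Sequence[TEInstance],
    cover: IntervalCoverage,
    min_frac: float,
) -> float | None:
    if not tes:
        return None
    hits = sum(1 for te in tes if cover.fraction(te.interval) >= min_frac)
    return hits / len(tes)


def class_overlap_by_orthology(
    ortho: Sequence[OrthologousTE],
    nonortho: Mapping[str, Sequence[TEInstance]],
    species_specific: Mapping[str, Sequence[TEInstance]],
    per_species_peaks: Mapping[str, Sequence[GenomicInterval]],
    min_frac: float = 0.5,
) -> pd.DataFrame:
    """Within-species overlap proportions per class x orthology category.

    For each species, TEs in each orthology category (orthologous /
    non-orthologous / species-specific) are overlapped with that species' own
    peak set (orthology of the peaks is not required). Cells with no TEs are
    reported as missing rather than zero; a chi-squared test compares
    overlapping/non-overlapping counts across orthology categories per class.
    """
    rows = []
    for sp in ("A", "B"):
        cover = IntervalCoverage(per_species_peaks[sp])
        ortho_tes = [o.te_a if sp == "A" else o.te_b for o in ortho]
        sets = {
            "orthologous": ortho_tes,
            "non_orthologous": list(nonortho[sp]),
            "species_specific": list(species_specific[sp]),
        }
        classes = sorted({te.te_class for group in sets.values() for te in group})
        for cls in classes:
            counts = {}
            for cat, group in sets.items():
                sub = [te for te in group if te.te_class == cls]
                prop = _overlap_proportion(sub, cover, min_frac)
                counts[cat] = (
                    None
                    if prop is None
                    else (round(prop * len(sub)), len(sub) - round(prop * len(sub)))
                )
                rows.append(
                    {
                        "species": sp,
                        "te_class": cls,
                        "orthology": cat,
                        "n": len(sub),
                        "proportion_overlapping": prop,
                    }
                )
            table = [v for v in counts.values() if v is not None and sum(v) > 0]
            if len(table) >= 2 and all(
                c > 0 for c in np.asarray(table).sum(axis=0)
            ):
                _, _, p = chi_squared_test(table)
            else:
                p = float("nan")
            for row in rows[-3:]:
                row["chi2_p_across_orthology"] = p
    return pd.DataFrame(rows)


def enrichment_by_class(calls: Sequence[SilencedTECall]) -> pd.DataFrame:
    """Per-class 2x2 chi-squared enrichment of H3K9me3 overlap versus the
    rest of the TE complement, BH-adjusted across classes."""
    classes = sorted({c.te_class for c in calls})
    if len(classes) < 2:
        raise ValueError("need at least two TE classes")
    overlapping = np.array([c.status != "non_overlapping" for c in calls])
    cls_arr = np.array([c.te_class for c in calls])
    rows = []
    for cls in classes:
        in_cls = cls_arr == cls
        table = [
            [int((in_cls & overlapping).sum()), int((in_cls & ~overlapping).sum())],
            [int((~in_cls & overlapping).sum()), int((~in_cls & ~overlapping).sum())],
        ]
        if min(sum(r) for r in table) == 0 or min(sum(c) for c in zip(*table)) == 0:
            rows.append(
                {"te_class": cls, "n": int(in_cls.sum()), "prop_overlap": float("nan"),
                 "background_prop": float("nan"), "chi2": float("nan"), "p": float("nan")}
            )
            continue
        x2, _, p = chi_squared_test(table)
        rows.append(
            {
                "te_class": cls,
                "n": int(in_cls.sum()),
                "prop_overlap": table[0][0] / (table[0][0] + table[0][1]),
                "background_prop": table[1][0] / (table[1][0] + table[1][1]),
                "chi2": x2,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    df["padj"] = np.nan
    if ok.any():
        df.loc[ok, "padj"] = bh_adjust(df.loc[ok, "p"].to_numpy())
    return df


def length_matched_control(
    nonoverlapping_tes: Sequence[TEInstance],
    regions: Sequence[GenomicInterval],
    target_median: int,
    chrom_sizes: Mapping[str, int],
    seed: int = 0,
    min_frac: float = 0.5,
) -> tuple[float, float]:
    """Re-test overlap after symmetrically extending non-overlapping TEs to
    the median length of H3K9me3-marked TEs.

    Each TE shorter than ``target_median`` is grown equally on both sides
    (an odd leftover base goes to a random side; clipped at chromosome
    ends), and the >= ``min_frac`` overlap rule is re-applied. Returns the
    original and extended overlapping proportions.
    """
    if not nonoverlapping_tes:
        raise ValueError("no TEs supplied")
    rng = np.random.default_rng(seed)
    cover = IntervalCoverage(regions)
    orig_hits = 0
    ext_hits = 0
    for te in nonoverlapping_tes:
        iv = te.interval
        if cover.fraction(iv) >= min_frac:
            orig_hits += 1
        grow = max(0, target_median - iv.length)
        left = grow // 2
        if grow % 2 == 1 and rng.random() < 0.5:
            left += 1
        start = max(0, iv.start - left)
        end = min(chrom_sizes[iv.chrom], iv.end + (grow - left))
        if cover.fraction(GenomicInterval(iv.chrom, start, end)) >= min_frac:
            ext_hits += 1
    n = len(nonoverlapping_tes)
    return orig_hits / n, ext_hits / n


def _tss_distance(iv: GenomicInterval, tss_sorted: Mapping[str, np.ndarray]) -> float:
    """Distance in bp to the closest TSS; 0 if a TSS falls inside the TE,
    else the gap between nearest edges (a TE ending 1 bp before a TSS is at
    distance 1)."""
    positions = tss_sorted.get(iv.chrom)
    if positions is None or positions.size == 0:
        return float("nan")
    idx = int(np.searchsorted(positions, iv.start))
    best = float("inf")
    for k in (idx - 1, idx, idx + 1):
        if 0 <= k < positions.size:
            t = int(positions[k])
            if iv.start <= t < iv.end:
                return 0.0
            best = min(best, iv.start - t if t < iv.start else t - iv.end + 1)
    return float(best)


def property_compare(
    calls: Sequence[SilencedTECall],
    prop: str,
    grouping: str = "category",
    tss_positions: Mapping[str, Sequence[int]] | None = None,
    split_threshold: float = 1.0,
) -> dict:
    """Compare a TE property (``length``, ``milliDiv`` or ``tss_distance``)
    across silencing groups.

    ``grouping='category'`` contrasts the four silencing categories (rank-sum
    between shared and non_overlapping); ``grouping='abs_log2fc_split'``
    contrasts overlapping TEs with |log2fc| below vs at-or-above
    ``split_threshold`` (default 1, i.e. two-fold). Groups with fewer than
    two members skip their contrast.
    """
    if prop not in ("length", "milliDiv", "tss_distance"):
        raise ValueError(f"unknown property {prop!r}")
    if prop == "tss_distance" and tss_positions is None:
        raise ValueError("tss_distance requires tss_positions")
    tss_sorted = None
    if tss_positions is not None:
        tss_sorted = {c: np.sort(np.asarray(p)) for c, p in tss_positions.items()}

    def value(call: SilencedTECall) -> float:
        if prop == "length":
            return call.interval.length
        if prop == "milliDiv":
            return call.milli_div
        return _tss_distance(call.interval, tss_sorted)

    if grouping == "category":
        groups: dict[str, list[float]] = defaultdict(list)
        for c in calls:
            groups[c.status].append(value(c))
        contrasts = [("shared", "non_overlapping")]
    elif grouping == "abs_log2fc_split":
        groups = defaultdict(list)
        for c in calls:
            if c.status == "non_overlapping" or not np.isfinite(c.log2fc):
                continue
            key = "low_divergence" if abs(c.log2fc) < split_threshold else "high_divergence"
            groups[key].append(value(c))
        contrasts = [("low_divergence", "high_divergence")]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    summary = {
        g: {
            "n": len(v),
            "median": float(np.median(v)) if v else float("nan"),
            "iqr": float(np.subtract(*np.percentile(v, [75, 25]))) if v else float("nan"),
        }
        for g, v in groups.items()
    }
    tests = {}
    for g1, g2 in contrasts:
        v1 = [x for x in groups.get(g1, []) if np.isfinite(x)]
        v2 = [x for x in groups.get(g2, []) if np.isfinite(x)]
        if len(v1) < 2 or len(v2) < 2:
            continue
        u, p = rank_sum_test(v1, v2)
        tests[f"{g1}_vs_{g2}"] = {"U": u, "p": p}
    return {"property": prop, "groups": summary, "tests": tests}


def annotate_overlap(
    calls: Sequence[SilencedTECall],
    annotation: Sequence[GenomicInterval],
    mode: str = "any_bp",
) -> dict:
    """Fraction of TEs per silencing category intersecting an annotation.

    ``any_bp`` counts a single shared base as a hit (chromatin-state rule);
    ``half_length`` requires >= 50% of the TE's length covered (functional-
    mark rule). Returns per-category proportions and a chi-squared test of
    hit/miss counts across categories.
    """
    if mode not in ("any_bp", "half_length"):
        raise ValueError(f"unknown mode {mode!r}")
    if not annotation:
        raise ValueError("empty annotation")
    cover = IntervalCoverage(annotation)
    tallies: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for c in calls:
        frac = cover.fraction(c.interval)
        hit = frac > 0 if mode == "any_bp" else frac >= 0.5
        tallies[c.status][0 if hit else 1] += 1
    props = {
        cat: hits / (hits + misses) for cat, (hits, misses) in tallies.items()
    }
    table = [v for v in tallies.values() if sum(v) > 0]
    p = float("nan")
    if len(table) >= 2:
        cols = np.asarray(table).sum(axis=0)
        if (cols > 0).all():
            _, _, p = chi_squared_test(table)
    return {"mode": mode, "proportions": props, "chi2_p": p}


def copy_number_vs_overlap(
    calls: Sequence[SilencedTECall],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Correlation between family copy number and the family's proportion of
    H3K9me3-marked instances, with a permutation p-value."""
    fams: dict[str, list[bool]] = defaultdict(list)
    for c in calls:
        fams[c.family].append(c.status != "non_overlapping")
    if len(fams) < 3:
        raise ValueError("need at least 3 TE families")
    names = sorted(fams)
    x = np.array([len(fams[f]) for f in names], dtype=float)
    y = np.array([np.mean(fams[f]) for f in names])
    return pearson_corr_permutation(x, y, n_perm=n_perm, seed=seed)
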