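"""Synthetic two-species cohorts with known ground truth.

The generator emulates the study design this pipeline targets: two closely
related genomes descended from a common ancestor (substitutions + indels,
with the exact base-level correspondence emitted as UCSC chains in both
directions), hierarchical TE annotations with per-instance consensus
divergence and orthologous / non-orthologous / species-specific instances,
per-individual ChIP and Input fragment cohorts with negative-binomial noise
and configurable shared vs species-specific H3K9me3 enrichment over silenced
TEs, and gene expression counts with a configurable coupling between
upstream species-specific silencing and expression divergence.

Every artifact is a deterministic function of ``SimulationConfig.seed``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .chainmap import ChainAlignment
from .core import GenomicInterval
from .genes import GeneModel
from .repeats import TE_CLASSES, TEInstance

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "GenomePair",
    "Cohort",
    "simulate_genome_pair",
    "simulate_te_annotations",
    "simulate_gene_models",
    "simulate_chip_fragments",
    "simulate_expression",
    "simulate_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# type catalogue: class -> family -> shared type names
_TE_CATALOG: dict[str, dict[str, list[str]]] = {
    "LINE": {"L1": ["L1PA3", "L1PA7"], "L2": ["L2a"]},
    "SINE": {"Alu": ["AluY", "AluSx"], "MIR": ["MIRb"]},
    "LTR": {"ERVK": ["HERVK9", "ERVK3"], "ERV1": ["HERVH", "HERVE"]},
    "DNA": {"hAT": ["Charlie1", "MER5A"], "TcMar": ["Tigger1"]},
    "SVA": {"SVA": ["SVA_A", "SVA_B", "SVA_D"]},
}
# species-restricted type names (analogous to SVA_E/F being human-only)
_SPECIFIC_TYPES: dict[str, dict[str, tuple[str, str]]] = {
    "A": {"SVA": ("SVA", "SVA_E"), "LINE": ("L1", "L1HS"), "SINE": ("Alu", "AluYa5"),
          "LTR": ("ERVK", "HERVK11")},
    "B": {"SVA": ("SVA", "SVA_ptg"), "LINE": ("L1", "L1Pt"), "SINE": ("Alu", "AluYpt"),
          "LTR": ("ERVK", "PtERV1")},
}

_TE_LEN = {"LINE": 600, "SINE": 300, "LTR": 400, "DNA": 250, "SVA": 1200}
_MILLIDIV_MEAN = {"LINE": 250, "SINE": 220, "LTR": 150, "DNA": 280, "SVA": 60}
_MILLIDIV_SD = 60.0
_MILLIDIV_SILENCED_SHIFT = -60.0  # silenced TEs are younger on average
_SILENCED_MIN_SEPARATION = 2000  # bp between silenced-TE midpoints
_SILENCED_HALO = 300  # bp kept free of other TE annotations around silenced TEs


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort. Defaults mirror the study design
    scaled to desk size: a 10 + 7 individual cohort, a ~1% substitution
    divergence, class-skewed silencing priors (SVA > LTR > LINE > SINE >
    DNA) and an 80% shared fraction among silenced TEs."""

    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 1_000_000
    substitution_rate: float = 0.01
    indel_rate: float = 1e-4
    mean_indel_len: float = 3.0
    n_te: int = 5000
    te_class_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "SINE": 0.35, "LINE": 0.35, "LTR": 0.18, "DNA": 0.10, "SVA": 0.02,
        }
    )
    te_silencing_prior: Mapping[str, float] = field(
        default_factory=lambda: {
            "SVA": 0.5, "LTR": 0.2, "LINE": 0.05, "SINE": 0.025, "DNA": 0.0125,
        }
    )
    shared_fraction: float = 0.8
    species_effect_log2fc: float = 2.0
    nb_dispersion: float = 0.2
    mean_frag_per_region: float = 50.0
    n_individuals_per_species: tuple[int, int] = (10, 7)
    n_genes: int = 500
    expression_coupling: float = 0.0
    expression_window: int = 10_000
    expression_null_sd: float = 0.3
    species_specific_te_rate: float = 0.1
    background_frag_per_kb: float = 3.0
    frag_len: int = 200

    def validate(self) -> None:
        if self.chrom_len <= 0 or self.n_chrom <= 0:
            raise ValueError("chromosome count and length must be positive")
        for name in ("substitution_rate", "indel_rate", "shared_fraction",
                     "species_specific_te_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if set(self.te_class_weights) - set(TE_CLASSES):
            raise ValueError("unknown TE class in te_class_weights")
        total = sum(self.te_class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"te_class_weights sum to {total}, expected 1")
        for cls, p in self.te_silencing_prior.items():
            if cls not in TE_CLASSES or not (0 <= p <= 1):
                raise ValueError(f"invalid silencing prior {cls}={p}")
        if min(self.n_individuals_per_species) < 1:
            raise ValueError("need at least one individual per species")
        if self.nb_dispersion < 0 or self.mean_frag_per_region <= 0:
            raise ValueError("NB parameters must be positive")

    @property
    def individuals(self) -> list[str]:
        n_a, n_b = self.n_individuals_per_species
        return [f"A{i + 1:02d}" for i in range(n_a)] + [
            f"B{i + 1:02d}" for i in range(n_b)
        ]

    @property
    def species_map(self) -> dict[str, str]:
        return {ind: ind[0] for ind in self.individuals}


@dataclass
class SimulatedTE:
    uid: str
    te_class: str
    family: str
    name: str
    silencing: str  # none / shared / speciesA_only / speciesB_only
    orthology: str  # orthologous / non_orthologous / species_specific
    te_a: TEInstance | None = None
    te_b: TEInstance | None = None


@dataclass
class GroundTruth:
    """Per-TE silencing and orthology labels and per-gene true expression
    effects, keyed by simulator-assigned uids."""

    te_by_uid: dict[str, SimulatedTE] = field(default_factory=dict)
    gene_effect: dict[str, float] = field(default_factory=dict)

    @property
    def te_silencing_label(self) -> dict[str, str]:
        return {uid: t.silencing for uid, t in self.te_by_uid.items()}

    @property
    def te_orthology_label(self) -> dict[str, str]:
        return {uid: t.orthology for uid, t in self.te_by_uid.items()}

    def uid_by_te_id(self) -> dict[str, str]:
        out = {}
        for uid, t in self.te_by_uid.items():
            for inst in (t.te_a, t.te_b):
                if inst is not None:
                    out[inst.te_id] = uid
        return out


@dataclass
class GenomePair:
    genome_a: dict[str, str]
    genome_b: dict[str, str]
    chains_ab: list[ChainAlignment]
    chains_ba: list[ChainAlignment]
    events: list[dict]
    # ancestor -> descendant coordinate maps (−1 = deleted), per chrom/lineage
    anc_maps: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def sizes_a(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome_a.items()}

    @property
    def sizes_b(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome_b.items()}


def _mutate_lineage(
    anc: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator,
    chrom: str, lineage: str, events: list[dict],
) -> tuple[np.ndarray, np.ndarray]:
    """Apply substitutions and indels to one lineage; return the descendant
    sequence (bytes array) and the ancestor->descendant coordinate map."""
    n = anc.size
    seq = anc.copy()
    sub_mask = rng.random(n) < cfg.substitution_rate
    if sub_mask.any():
        idx = np.flatnonzero(sub_mask)
        old = np.searchsorted(_BASES, seq[idx])  # _BASES sorted A<C<G<T
        new = (old + rng.integers(1, 4, idx.size)) % 4
        seq[idx] = _BASES[new]
        events.append(
            {"lineage": lineage, "chrom": chrom, "type": "sub", "n": int(idx.size)}
        )

    n_indels = rng.binomial(n, cfg.indel_rate)
    positions = np.sort(rng.choice(n, size=n_indels, replace=False))
    lengths = rng.geometric(1.0 / cfg.mean_indel_len, size=n_indels)
    is_del = rng.random(n_indels) < 0.5

    deleted = np.zeros(n, dtype=bool)
    insertions: dict[int, np.ndarray] = {}
    for pos, length, d in zip(positions, lengths, is_del):
        if d:
            deleted[pos : pos + length] = True
            events.append(
                {"lineage": lineage, "chrom": chrom, "type": "del",
                 "anc_pos": int(pos), "length": int(length)}
            )
        else:
            ins = _BASES[rng.integers(0, 4, int(length))]
            insertions[int(pos)] = insertions.get(int(pos), np.array([], dtype="S1"))
            insertions[int(pos)] = np.concatenate([insertions[int(pos)], ins])
            events.append(
                {"lineage": lineage, "chrom": chrom, "type": "ins",
                 "anc_pos": int(pos), "length": int(length)}
            )

    base_idx = np.cumsum(~deleted) - 1
    ins_shift = np.zeros(n, dtype=np.int64)
    for pos, ins in insertions.items():
        # insertion after ancestor base `pos` shifts later positions
        if pos + 1 < n:
            ins_shift[pos + 1] += len(ins)
    ins_shift = np.cumsum(ins_shift)
    anc2desc = np.where(deleted, -1, base_idx + ins_shift)

    pieces = []
    prev = 0
    boundaries = sorted(insertions)
    kept = ~deleted
    for pos in boundaries:
        pieces.append(seq[prev : pos + 1][kept[prev : pos + 1]])
        pieces.append(insertions[pos])
        prev = pos + 1
    pieces.append(seq[prev:][kept[prev:]])
    desc = np.concatenate(pieces) if pieces else seq[kept]
    return desc, anc2desc


def _chain_from_maps(
    chrom: str,
    map_a: np.ndarray,
    map_b: np.ndarray,
    len_a: int,
    len_b: int,
    chain_id: int,
) -> ChainAlignment | None:
    aligned = np.flatnonzero((map_a >= 0) & (map_b >= 0))
    if aligned.size == 0:
        return None
    da = map_a[aligned]
    db = map_b[aligned]
    breaks = np.flatnonzero(
        (np.diff(aligned) != 1) | (np.diff(da) != 1) | (np.diff(db) != 1)
    )
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [aligned.size - 1]])

    blocks = []
    for i, (s, e) in enumerate(zip(starts, ends)):
        size = int(e - s + 1)
        if i < len(starts) - 1:
            ds = int(da[starts[i + 1]] - (da[e] + 1))
            dt = int(db[starts[i + 1]] - (db[e] + 1))
        else:
            ds = dt = 0
        blocks.append((size, ds, dt))
    chain = ChainAlignment(
        score=float(aligned.size),
        src_chrom=chrom, src_size=len_a, src_strand="+",
        src_start=int(da[0]), src_end=int(da[-1]) + 1,
        tgt_chrom=chrom, tgt_size=len_b, tgt_strand="+",
        tgt_start=int(db[0]), tgt_end=int(db[-1]) + 1,
        blocks=blocks, chain_id=chain_id,
    )
    chain.validate()
    return chain


def simulate_genome_pair(cfg: SimulationConfig) -> GenomePair:
    """Generate two descendant genomes from a common ancestor plus the exact
    chain alignments in both directions."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    genome_a: dict[str, str] = {}
    genome_b: dict[str, str] = {}
    chains_ab: list[ChainAlignment] = []
    events: list[dict] = []
    anc_maps: dict[str, dict[str, np.ndarray]] = {}
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        anc = _BASES[rng.integers(0, 4, cfg.chrom_len)]
        desc_a, map_a = _mutate_lineage(anc, cfg, rng, chrom, "A", events)
        desc_b, map_b = _mutate_lineage(anc, cfg, rng, chrom, "B", events)
        genome_a[chrom] = desc_a.tobytes().decode()
        genome_b[chrom] = desc_b.tobytes().decode()
        anc_maps[chrom] = {"A": map_a, "B": map_b}
        chain = _chain_from_maps(
            chrom, map_a, map_b, desc_a.size, desc_b.size, chain_id=c + 1
        )
        if chain is not None:
            chains_ab.append(chain)
    chains_ba = [c.invert() for c in chains_ab]
    return GenomePair(genome_a, genome_b, chains_ab, chains_ba, events, anc_maps)


def _sample_milli_div(
    rng: np.random.Generator, te_class: str, silenced: bool
) -> float:
    mean = _MILLIDIV_MEAN[te_class] + (_MILLIDIV_SILENCED_SHIFT if silenced else 0.0)
    a, b = (0 - mean) / _MILLIDIV_SD, (400 - mean) / _MILLIDIV_SD
    return float(truncnorm.rvs(a, b, loc=mean, scale=_MILLIDIV_SD, random_state=rng))


def _sample_length(rng: np.random.Generator, te_class: str) -> int:
    mean = _TE_LEN[te_class]
    length = int(rng.lognormal(np.log(mean), 0.4))
    return int(np.clip(length, 50, 5000))


class _SeparationIndex:
    """Bookkeeping for silenced-TE placements, per genome: minimum midpoint
    separation between silenced TEs and an annotation-free halo around them."""

    def __init__(self) -> None:
        self._mids: dict[tuple[str, str], list[int]] = {}
        self._spans: dict[tuple[str, str], list[tuple[int, int]]] = {}

    def mid_ok(self, genome: str, chrom: str, mid: int, min_sep: int) -> bool:
        mids = self._mids.get((genome, chrom), [])
        i = bisect.bisect_left(mids, mid)
        for k in (i - 1, i):
            if 0 <= k < len(mids) and abs(mids[k] - mid) < min_sep:
                return False
        return True

    def span_clear(self, genome: str, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) stays clear of all silenced spans + halo."""
        spans = self._spans.get((genome, chrom), [])
        i = bisect.bisect_left(spans, (start, start))
        for k in (i - 1, i, i + 1):
            if 0 <= k < len(spans):
                s, e = spans[k]
                if start < e + _SILENCED_HALO and s - _SILENCED_HALO < end:
                    return False
        return True

    def add(self, genome: str, chrom: str, start: int, end: int) -> None:
        mids = self._mids.setdefault((genome, chrom), [])
        bisect.insort(mids, (start + end) // 2)
        spans = self._spans.setdefault((genome, chrom), [])
        bisect.insort(spans, (start, end))


def simulate_te_annotations(
    cfg: SimulationConfig, pair: GenomePair
) -> tuple[list[TEInstance], list[TEInstance], GroundTruth]:
    """Place TEs with class/family/type hierarchy, milliDiv, orthology and
    silencing ground truth.

    Orthologous TEs sit on ancestor segments retained contiguously in both
    lineages, so their two coordinate sets correspond exactly under the
    chains. A fraction ``species_specific_te_rate`` of TEs exists in a single
    genome; half of those carry a type name absent from the other species'
    table (species-specific), half a shared name (plain non-orthologous).
    Silenced TEs are placed with a minimum mutual separation so that distinct
    silenced loci produce distinct H3K9me3 domains at this genome scale.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    classes = sorted(cfg.te_class_weights)
    weights = np.array([cfg.te_class_weights[c] for c in classes])
    chroms = sorted(pair.genome_a)
    truth = GroundTruth()
    sep = _SeparationIndex()

    # Pass 1: draw every TE's attributes.
    records = []
    for i in range(cfg.n_te):
        te_class = classes[rng.choice(len(classes), p=weights)]
        single_genome = rng.random() < cfg.species_specific_te_rate
        silenced = rng.random() < cfg.te_silencing_prior.get(te_class, 0.0)
        if single_genome:
            genome = "A" if rng.random() < 0.5 else "B"
            unique_name = rng.random() < 0.5 and te_class in _SPECIFIC_TYPES[genome]
            if unique_name:
                family, name = _SPECIFIC_TYPES[genome][te_class]
                orthology = "species_specific"
            else:
                family = rng.choice(sorted(_TE_CATALOG[te_class]))
                name = rng.choice(_TE_CATALOG[te_class][family])
                orthology = "non_orthologous"
            silencing = f"species{genome}_only" if silenced else "none"
        else:
            genome = "both"
            family = rng.choice(sorted(_TE_CATALOG[te_class]))
            name = rng.choice(_TE_CATALOG[te_class][family])
            orthology = "orthologous"
            # shared vs species-specific assigned by stratified quota below
            silencing = "_silenced_ortho" if silenced else "none"
        length = _sample_length(rng, te_class)
        mdiv = _sample_milli_div(rng, te_class, silenced)
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(
            {"i": i, "te_class": te_class, "genome": genome, "family": family,
             "name": name, "orthology": orthology, "silencing": silencing,
             "length": length, "mdiv": mdiv, "strand": strand}
        )

    # Stratified assignment of the shared / species-specific split among
    # silenced orthologous TEs: the configured shared_fraction is realized
    # exactly up to rounding (direction split as even as possible), with a
    # random permutation deciding which TE gets which label.
    pending = [r for r in records if r["silencing"] == "_silenced_ortho"]
    if pending:
        n_sil = len(pending)
        n_shared = int(round(cfg.shared_fraction * n_sil))
        n_specific = n_sil - n_shared
        n_a = n_specific // 2 + int(rng.random() < 0.5 and n_specific % 2 == 1)
        labels = (["shared"] * n_shared + ["speciesA_only"] * n_a
                  + ["speciesB_only"] * (n_specific - n_a))
        for rec, label in zip(pending, rng.permutation(labels)):
            rec["silencing"] = str(label)

    # Pass 2: place silenced TEs first (mutual separation), then the rest
    # (kept out of a halo around silenced loci so each silenced locus forms
    # its own clean H3K9me3 domain).
    placements: dict[int, tuple[GenomicInterval | None, GenomicInterval | None]] = {}
    ordered = [r for r in records if r["silencing"] != "none"] + [
        r for r in records if r["silencing"] == "none"
    ]
    for rec in ordered:
        silenced = rec["silencing"] != "none"
        length = rec["length"]
        placed = None
        for _attempt in range(1000):
            chrom = chroms[rng.integers(0, len(chroms))]
            if rec["orthology"] == "orthologous":
                map_a = pair.anc_maps[chrom]["A"]
                map_b = pair.anc_maps[chrom]["B"]
                anc_len = map_a.size
                if length >= anc_len:
                    continue
                p = int(rng.integers(0, anc_len - length))
                seg_a = map_a[p : p + length]
                seg_b = map_b[p : p + length]
                if (seg_a < 0).any() or (seg_b < 0).any():
                    continue
                if (np.diff(seg_a) != 1).any() or (np.diff(seg_b) != 1).any():
                    continue
                iv_a = GenomicInterval(chrom, int(seg_a[0]), int(seg_a[-1]) + 1)
                iv_b = GenomicInterval(chrom, int(seg_b[0]), int(seg_b[-1]) + 1)
                if silenced:
                    mid_a = (iv_a.start + iv_a.end) // 2
                    mid_b = (iv_b.start + iv_b.end) // 2
                    if not (
                        sep.mid_ok("A", chrom, mid_a, _SILENCED_MIN_SEPARATION)
                        and sep.mid_ok("B", chrom, mid_b, _SILENCED_MIN_SEPARATION)
                    ):
                        continue
                    sep.add("A", chrom, iv_a.start, iv_a.end)
                    sep.add("B", chrom, iv_b.start, iv_b.end)
                else:
                    if not (
                        sep.span_clear("A", chrom, iv_a.start, iv_a.end)
                        and sep.span_clear("B", chrom, iv_b.start, iv_b.end)
                    ):
                        continue
                placed = (iv_a, iv_b)
            else:
                genome = rec["genome"]
                glen = len(
                    (pair.genome_a if genome == "A" else pair.genome_b)[chrom]
                )
                if length >= glen:
                    continue
                start = int(rng.integers(0, glen - length))
                iv = GenomicInterval(chrom, start, start + length)
                if silenced:
                    mid = (iv.start + iv.end) // 2
                    if not sep.mid_ok(genome, chrom, mid, _SILENCED_MIN_SEPARATION):
                        continue
                    sep.add(genome, chrom, iv.start, iv.end)
                else:
                    if not sep.span_clear(genome, chrom, iv.start, iv.end):
                        continue
                placed = (iv, None) if genome == "A" else (None, iv)
            break
        if placed is None:
            raise RuntimeError(
                f"could not place TE {rec['i']} after bounded retries; "
                "genome too small or too fragmented for the configuration"
            )
        placements[rec["i"]] = placed

    rmsk_a: list[TEInstance] = []
    rmsk_b: list[TEInstance] = []
    for rec in records:
        iv_a, iv_b = placements[rec["i"]]
        uid = f"TE{rec['i']:06d}"
        te_a = te_b = None
        if iv_a is not None:
            te_a = TEInstance(
                GenomicInterval(iv_a.chrom, iv_a.start, iv_a.end, rec["strand"]),
                rec["name"], rec["family"], rec["te_class"], rec["mdiv"], species="A",
            )
            rmsk_a.append(te_a)
        if iv_b is not None:
            te_b = TEInstance(
                GenomicInterval(iv_b.chrom, iv_b.start, iv_b.end, rec["strand"]),
                rec["name"], rec["family"], rec["te_class"], rec["mdiv"], species="B",
            )
            rmsk_b.append(te_b)
        truth.te_by_uid[uid] = SimulatedTE(
            uid, rec["te_class"], rec["family"], rec["name"], rec["silencing"],
            rec["orthology"], te_a, te_b,
        )

    key = lambda te: (te.interval.chrom, te.interval.start, te.interval.end)
    rmsk_a.sort(key=key)
    rmsk_b.sort(key=key)
    return rmsk_a, rmsk_b, truth


def simulate_gene_models(
    cfg: SimulationConfig, pair: GenomePair
) -> list[GeneModel]:
    """Place gene models with 1-3 transcripts on genome A."""
    rng = np.random.default_rng([cfg.seed, 3])
    chroms = sorted(pair.genome_a)
    genes = []
    for g in range(cfg.n_genes):
        chrom = chroms[rng.integers(0, len(chroms))]
        glen = len(pair.genome_a[chrom])
        strand = "+" if rng.random() < 0.5 else "-"
        margin = min(50_000, glen // 5)
        anchor = int(rng.integers(margin, glen - margin))
        n_tx = int(rng.integers(1, 4))
        transcripts = []
        for _ in range(n_tx):
            s = anchor + int(rng.integers(0, 2000))
            e = s + int(rng.integers(2000, 20_000))
            transcripts.append((s, min(e, glen)))
        genes.append(
            GeneModel(f"G{g:05d}", chrom, strand, transcripts, orthologous=True)
        )
    return genes


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson NB draws with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _te_enrichment_rates(
    cfg: SimulationConfig, truth: GroundTruth
) -> dict[str, list[tuple[GenomicInterval, float]]]:
    """Per-genome list of (TE interval, mean enriched fragments per
    individual) for all silenced TEs."""
    mult = 2.0 ** cfg.species_effect_log2fc
    rates: dict[str, list[tuple[GenomicInterval, float]]] = {"A": [], "B": []}
    for t in truth.te_by_uid.values():
        if t.silencing == "none":
            continue
        r = cfg.mean_frag_per_region
        for genome, inst in (("A", t.te_a), ("B", t.te_b)):
            if inst is None:
                continue
            rate = r
            if t.silencing == f"species{genome}_only" and t.orthology == "orthologous":
                rate = r * mult
            rates[genome].append((inst.interval, rate))
    return rates


def simulate_chip_fragments(
    cfg: SimulationConfig,
    pair: GenomePair,
    truth: GroundTruth,
) -> tuple[dict[tuple[str, str], list[GenomicInterval]], dict[str, float]]:
    """Per-individual ChIP and Input fragment sets.

    Input fragments are uniform over the individual's genome. ChIP fragments
    mix a uniform background with enrichment over silenced TEs: each silenced
    TE contributes NB-distributed fragment counts with mean
    ``mean_frag_per_region`` (times ``2**species_effect_log2fc`` in the
    favored species for species-specific labels), scaled by a lognormal
    per-individual depth factor. Returns ``{(individual, assay): fragments}``
    and the depth factors.
    """
    cfg.validate()
    if not cfg.individuals:
        raise ValueError("no individuals configured")
    rates = _te_enrichment_rates(cfg, truth)
    genomes = {"A": pair.genome_a, "B": pair.genome_b}
    out: dict[tuple[str, str], list[GenomicInterval]] = {}
    depths: dict[str, float] = {}
    half = cfg.frag_len // 2

    for idx, indiv in enumerate(cfg.individuals):
        rng = np.random.default_rng([cfg.seed, 2, idx])
        sp = indiv[0]
        genome = genomes[sp]
        glen_total = sum(len(s) for s in genome.values())
        depth = float(rng.lognormal(0.0, 0.15))
        depths[indiv] = depth

        bg_mean = cfg.background_frag_per_kb * glen_total / 1000.0
        chip: list[GenomicInterval] = []
        n_bg = rng.poisson(bg_mean * depth)
        chip.extend(_uniform_frags(rng, genome, n_bg, cfg.frag_len))
        for iv, rate in rates[sp]:
            n = int(_nb_counts(rng, np.array([rate * depth]), cfg.nb_dispersion)[0])
            if n == 0:
                continue
            mids = rng.integers(iv.start, iv.end, n)
            glen = len(genome[iv.chrom])
            for m in mids:
                s = int(np.clip(m - half, 0, max(1, glen - cfg.frag_len)))
                chip.append(GenomicInterval(iv.chrom, s, min(s + cfg.frag_len, glen)))
        chip.sort(key=lambda f: (f.chrom, f.start))
        out[(indiv, "chip")] = chip

        exp_chip_total = bg_mean + sum(r for _, r in rates[sp])
        n_input = rng.poisson(exp_chip_total * depth)
        inp = _uniform_frags(rng, genome, n_input, cfg.frag_len)
        inp.sort(key=lambda f: (f.chrom, f.start))
        out[(indiv, "input")] = inp
    return out, depths


def _uniform_frags(
    rng: np.random.Generator, genome: Mapping[str, str], n: int, frag_len: int
) -> list[GenomicInterval]:
    chroms = sorted(genome)
    lens = np.array([len(genome[c]) for c in chroms], dtype=float)
    probs = lens / lens.sum()
    which = rng.choice(len(chroms), size=n, p=probs)
    frags = []
    for ci in which:
        chrom = chroms[ci]
        glen = int(lens[ci])
        s = int(rng.integers(0, max(1, glen - frag_len)))
        frags.append(GenomicInterval(chrom, s, min(s + frag_len, glen)))
    return frags


def simulate_expression(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Gene x individual NB expression counts with silencing coupling.

    A gene whose upstream ``expression_window`` (genome-A coordinates)
    contains a species-specifically silenced orthologous TE receives a true
    species effect ``expression_coupling * direction`` (direction +1 when
    silencing is higher in species A); all other genes draw their effect from
    a centred normal null. Also returns per-TE-type agglomerated read/length
    tables and per-individual total exonic reads for RPKM work.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 4])

    spec_tes: dict[str, list[tuple[int, int, int]]] = {}
    for t in truth.te_by_uid.values():
        if t.orthology != "orthologous" or t.te_a is None:
            continue
        if t.silencing not in ("speciesA_only", "speciesB_only"):
            continue
        direction = 1 if t.silencing == "speciesA_only" else -1
        iv = t.te_a.interval
        spec_tes.setdefault(iv.chrom, []).append((iv.start, iv.end, direction))

    effects = {}
    for gene in genes:
        if gene.strand == "+":
            w_start, w_end = max(0, gene.tss - cfg.expression_window), gene.tss
        else:
            w_start, w_end = gene.tss, gene.tss + cfg.expression_window
        direction = 0
        for s, e, d in spec_tes.get(gene.chrom, []):
            if s < w_end and e > w_start:
                direction = d
                break
        if direction != 0:
            effects[gene.gene_id] = cfg.expression_coupling * direction
        else:
            effects[gene.gene_id] = float(rng.normal(0.0, cfg.expression_null_sd))
    truth.gene_effect = dict(effects)

    individuals = cfg.individuals
    base = rng.lognormal(np.log(100.0), 1.0, len(genes))
    depth = rng.lognormal(0.0, 0.1, len(individuals))
    counts = np.zeros((len(genes), len(individuals)), dtype=int)
    eff = np.array([effects[g.gene_id] for g in genes])
    for j, indiv in enumerate(individuals):
        sign = 0.5 if indiv[0] == "A" else -0.5
        mu = base * 2.0 ** (sign * eff) * depth[j]
        counts[:, j] = _nb_counts(rng, mu, cfg.nb_dispersion)
    gene_counts = pd.DataFrame(
        counts, index=[g.gene_id for g in genes], columns=individuals
    )

    # Per-TE-type agglomerated expression: a handful of types transcribed
    type_rows = []
    total_exonic = {
        sp: 1e7 for sp in ("A", "B")
    }
    agg: dict[tuple[str, str], float] = {}
    for t in truth.te_by_uid.values():
        for sp, inst in (("A", t.te_a), ("B", t.te_b)):
            if inst is not None:
                agg[(sp, t.name)] = agg.get((sp, t.name), 0.0) + inst.interval.length
    expressed_types = {"HERVH", "SVA_E", "SVA_ptg"}
    for (sp, name), length in sorted(agg.items()):
        if name in expressed_types:
            rpkm_target = float(rng.uniform(1.5, 5.0))
        else:
            rpkm_target = float(rng.uniform(0.01, 0.5))
        reads = rpkm_target * length * total_exonic[sp] / 1e9
        type_rows.append(
            {"species": sp, "te_type": name, "reads": reads, "length": length}
        )
    te_type_reads = pd.DataFrame(type_rows)
    return gene_counts, te_type_reads, total_exonic


@dataclass
class Cohort:
    """Everything one simulated study produces."""

    config: SimulationConfig
    pair: GenomePair
    rmsk_a: list[TEInstance]
    rmsk_b: list[TEInstance]
    truth: GroundTruth
    fragments: dict[tuple[str, str], list[GenomicInterval]]
    depths: dict[str, float]
    genes: list[GeneModel]
    gene_counts: pd.DataFrame
    te_type_reads: pd.DataFrame
    total_exonic_reads: dict[str, float]

    @property
    def species_map(self) -> dict[str, str]:
        return self.config.species_map


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    """Run all generator stages under one seed."""
    pair = simulate_genome_pair(cfg)
    rmsk_a, rmsk_b, truth = simulate_te_annotations(cfg, pair)
    genes = simulate_gene_models(cfg, pair)
    fragments, depths = simulate_chip_fragments(cfg, pair, truth)
    gene_counts, te_type_reads, total_exonic = simulate_expression(cfg, genes, truth)
    return Cohort(
        config=cfg,
        pair=pair,
        rmsk_a=rmsk_a,
        rmsk_b=rmsk_b,
        truth=truth,
        fragments=fragments,
        depths=depths,
        genes=genes,
        gene_counts=gene_counts,
        te_type_reads=te_type_reads,
        total_exonic_reads=total_exonic,
    )
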