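import numpy as np
import pytest

from orthosilence import (
    ChainAlignment,
    GenomicInterval,
    PipelineConfig,
    SimulationConfig,
    run_pipeline,
    simulate_cohort,
)


def identity_chain(chrom: str = "chr1", size: int = 1_000_000) -> ChainAlignment:
    return ChainAlignment(
        score=size,
        src_chrom=chrom, src_size=size, src_strand="+", src_start=0, src_end=size,
        tgt_chrom=chrom, tgt_size=size, tgt_strand="+", tgt_start=0, tgt_end=size,
        blocks=[(size, 0, 0)], chain_id=1,
    )


def multiblock_chain() -> ChainAlignment:
    """Hand-built 4-block chain with assorted source/target gaps."""
    blocks = [(500, 50, 0), (300, 0, 120), (700, 30, 30), (450, 0, 0)]
    src_span = sum(s + ds for s, ds, _ in blocks)
    tgt_span = sum(s + dt for s, _, dt in blocks)
    chain = ChainAlignment(
        score=1950,
        src_chrom="chr1", src_size=10_000, src_strand="+",
        src_start=100, src_end=100 + src_span,
        tgt_chrom="chr1", tgt_size=10_000, tgt_strand="+",
        tgt_start=200, tgt_end=200 + tgt_span,
        blocks=blocks, chain_id=7,
    )
    chain.validate()
    return chain


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_chrom=1,
        chrom_len=300_000,
        n_te=600,
        n_individuals_per_species=(5, 4),
        n_genes=120,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_cfg):
    return run_pipeline(PipelineConfig(simulation=small_cfg))


def brute_force_lift(iv: GenomicInterval, chain: ChainAlignment):
    """Independent per-base mapper: map every base of ``iv`` through the
    chain's aligned blocks; return (mapped fraction, target envelope)."""
    mapped = []
    for pos in range(iv.start, iv.end):
        s = chain.src_start
        t = chain.tgt_start
        for size, ds, dt in chain.blocks:
            if s <= pos < s + size:
                mapped.append(t + (pos - s))
                break
            s += size + ds
            t += size + dt
    if not mapped:
        return 0.0, None
    frac = len(mapped) / iv.length
    return frac, GenomicInterval(chain.tgt_chrom, min(mapped), max(mapped) + 1)


def nb_matrix(rng, n_feat, n_a, n_b, mu_log_mean=np.log(100), alpha=0.2,
              effect_rows=0, effect_fc=2.0, balanced=False):
    """NB count matrix helper for statistics tests."""
    import pandas as pd

    cols = [f"A{i:02d}" for i in range(n_a)] + [f"B{i:02d}" for i in range(n_b)]
    mu = rng.lognormal(mu_log_mean, 0.5, n_feat)
    M = np.tile(mu[:, None], (1, n_a + n_b))
    if effect_rows:
        if balanced:
            half = effect_rows // 2
            M[:half, :n_a] *= effect_fc
            M[half:effect_rows, n_a:] *= effect_fc
        else:
            M[:effect_rows, :n_a] *= effect_fc
    if alpha > 0:
        lam = rng.gamma(1 / alpha, M * alpha)
    else:
        lam = M
    K = rng.poisson(lam)
    species = {c: c[0] for c in cols}
    return pd.DataFrame(K, columns=cols), species
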