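"""Count-based differential statistics.

A self-contained negative-binomial differential engine used for both ChIP
region counts and RNA gene counts: median-of-ratios size factors,
method-of-moments dispersion estimation with trend shrinkage, per-feature NB
regression with a two-level species design fitted by IRLS, Wald tests,
independent filtering and Benjamini-Hochberg control. Generic two-sample and
association tests used across the analyses (rank-sum, chi-squared,
permutation-based Pearson correlation) live here too.

Model per feature g and individual j with species indicator x_j:

    K_gj ~ NB(mu_gj, alpha_g),   log mu_gj = log s_j + beta0_g + beta_g x_j

``beta_g / ln 2`` is reported as the log2 fold change, positive meaning
higher counts in species A.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DifferentialResult",
    "DispersionModel",
    "size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "bh_adjust",
    "independent_filter",
    "classify_enrichment",
    "rank_sum_test",
    "chi_squared_test",
    "pearson_corr_permutation",
]

_ALPHA_FLOOR = 1e-8
_MAX_ITER = 100
_ETA_CLIP = 30.0


@dataclass
class DifferentialResult:
    feature_id: str
    base_mean: float
    log2fc: float
    se: float
    wald_p: float
    padj: float = float("nan")
    category: str = "shared"
    tested: bool = True


@dataclass
class DispersionModel:
    """Per-feature NB dispersions with a 1/mu trend and geometric shrinkage.

    ``alpha(mu) = a1 / mu + a0`` is fitted by least squares to the raw
    method-of-moments estimates; the final dispersion is
    ``exp(w * log(raw) + (1 - w) * log(trend))``.
    """

    raw: np.ndarray
    trend_a0: float
    trend_a1: float
    shrunken: np.ndarray
    weight: float = 0.5
    feature_means: np.ndarray = field(default_factory=lambda: np.array([]))


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per individual (column).

    Each count is divided by its feature's geometric mean across individuals;
    the per-column median of those ratios, over features positive in every
    individual, is the size factor.
    """
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in all individuals; "
            "apply occupancy filtering first"
        )
    sub = counts.loc[positive].to_numpy(dtype=float)
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    log_ratios = np.log(sub) - log_geo
    sf = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(sf, index=counts.columns)


def _species_masks(columns, species: dict[str, str]) -> tuple[np.ndarray, np.ndarray]:
    labels = np.array([species[c] for c in columns])
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"need exactly two species, got {groups}")
    # species "A" (first sorted label) carries the positive coefficient
    return labels == groups[0], labels == groups[1]


def estimate_dispersions(
    counts: pd.DataFrame,
    sf: pd.Series,
    species: dict[str, str],
    weight: float = 0.5,
) -> DispersionModel:
    """Method-of-moments dispersions on normalized counts, pooled within
    species, shrunk toward a fitted ``a1/mu + a0`` trend."""
    mask_a, mask_b = _species_masks(counts.columns, species)
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("need at least 3 individuals per species")
    q = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]

    alphas = []
    for mask in (mask_a, mask_b):
        sub = q[:, mask]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu) / mu**2
        a[~np.isfinite(a)] = _ALPHA_FLOOR
        alphas.append(a)
    raw = np.maximum(np.mean(alphas, axis=0), _ALPHA_FLOOR)

    mu_all = q.mean(axis=1)
    ok = mu_all > 0
    if ok.sum() >= 2:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mu_all[ok]])
        coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
        a0 = max(float(coef[0]), _ALPHA_FLOOR)
        a1 = max(float(coef[1]), 0.0)
    else:
        a0, a1 = float(np.median(raw)), 0.0
    with np.errstate(divide="ignore"):
        trend = np.maximum(a1 / np.maximum(mu_all, 1e-12) + a0, _ALPHA_FLOOR)
    shrunken = np.exp(weight * np.log(raw) + (1 - weight) * np.log(trend))
    return DispersionModel(
        raw=raw,
        trend_a0=a0,
        trend_a1=a1,
        shrunken=shrunken,
        weight=weight,
        feature_means=mu_all,
    )


def nb_wald_test(
    counts: pd.DataFrame,
    sf: pd.Series,
    disp: DispersionModel,
    species: dict[str, str],
) -> list[DifferentialResult]:
    """Per-feature NB regression with a species effect; Wald z-test.

    All features are fitted simultaneously by vectorized IRLS. Features whose
    fit does not converge (or is degenerate, e.g. all-zero counts) are
    returned with ``tested=False`` and a missing p-value.
    """
    mask_a, _ = _species_masks(counts.columns, species)
    x = mask_a.astype(float)
    K = counts.to_numpy(dtype=float)
    s = sf.to_numpy(dtype=float)
    n_feat, n_samp = K.shape
    alpha = disp.shrunken[:, None]
    offset = np.log(s)[None, :]

    q_mean = np.maximum((K / s[None, :]).mean(axis=1), 1e-8)
    beta0 = np.log(q_mean)
    beta1 = np.zeros(n_feat)

    converged = np.zeros(n_feat, dtype=bool)
    for _ in range(_MAX_ITER):
        eta = np.clip(offset + beta0[:, None] + beta1[:, None] * x[None, :],
                      -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = eta - offset + (K - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x[None, :]).sum(axis=1)
        swxx = (w * x[None, :] ** 2).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * x[None, :] * z).sum(axis=1)
        det = sw * swxx - swx**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        new0 = (swxx * swz - swx * swxz) / det
        new1 = (sw * swxz - swx * swz) / det
        new0 = np.clip(new0, -_ETA_CLIP, _ETA_CLIP)
        new1 = np.clip(new1, -2 * _ETA_CLIP, 2 * _ETA_CLIP)
        delta = np.maximum(np.abs(new0 - beta0), np.abs(new1 - beta1))
        beta0, beta1 = new0, new1
        converged = np.isfinite(delta) & (delta < 1e-8)
        if converged.all():
            break

    eta = np.clip(offset + beta0[:, None] + beta1[:, None] * x[None, :],
                  -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    sw = w.sum(axis=1)
    swx = (w * x[None, :]).sum(axis=1)
    swxx = (w * x[None, :] ** 2).sum(axis=1)
    det = sw * swxx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = sw / det
    se = np.sqrt(var_b1)
    zstat = beta1 / se
    pvals = 2.0 * sps.norm.sf(np.abs(zstat))
    base_mean = (K / s[None, :]).mean(axis=1)

    results = []
    for i, fid in enumerate(counts.index):
        ok = (
            bool(converged[i])
            and np.isfinite(se[i])
            and se[i] > 0
            and np.isfinite(pvals[i])
        )
        results.append(
            DifferentialResult(
                feature_id=str(fid),
                base_mean=float(base_mean[i]),
                log2fc=float(beta1[i] / math.log(2)) if ok else float("nan"),
                se=float(se[i] / math.log(2)) if ok else float("nan"),
                wald_p=float(pvals[i]) if ok else float("nan"),
                tested=ok,
            )
        )
    return results


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def independent_filter(
    results: Sequence[DifferentialResult],
    quantile_grid: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    alpha: float = 0.01,
) -> list[DifferentialResult]:
    """Filter low-mean features before BH, keeping the base-mean quantile
    threshold that maximizes rejections at ``alpha``.

    Features below the chosen threshold (and untested features) receive no
    adjusted p-value and are flagged ``tested=False``.
    """
    results = list(results)
    tested = [r for r in results if r.tested]
    if not tested:
        return results
    base = np.array([r.base_mean for r in tested])
    pvals = np.array([r.wald_p for r in tested])

    grid = sorted(quantile_grid)
    best_thresh, best_rej = None, -1
    if not grid:
        grid = [0.0]
    for theta in grid:
        thresh = np.quantile(base, theta)
        keep = base >= thresh
        if keep.sum() == 0:
            continue
        padj = bh_adjust(pvals[keep])
        rej = int((padj < alpha).sum())
        if rej > best_rej:
            best_rej, best_thresh = rej, thresh
    keep = base >= best_thresh
    padj = bh_adjust(pvals[keep])
    it = iter(padj)
    for r, k in zip(tested, keep):
        if k:
            r.padj = float(next(it))
        else:
            r.padj = float("nan")
            r.tested = False
    return results


def classify_enrichment(
    results: Sequence[DifferentialResult], alpha: float = 0.01
) -> list[str]:
    """Label each feature ``A_enriched`` / ``B_enriched`` / ``shared``.

    Features without an adjusted p-value (filtered or unfitted) count as
    ``shared`` so that category proportions keep the full retained-feature
    denominator.
    """
    labels = []
    for r in results:
        if r.tested and np.isfinite(r.padj) and r.padj < alpha:
            label = "A_enriched" if r.log2fc > 0 else "B_enriched"
        else:
            label = "shared"
        r.category = label
        labels.append(label)
    return labels


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney rank-sum test, two-sided.

    Exact by full enumeration of group assignments (midranks, so ties are
    handled) when the combined sample size is at most 12; otherwise the
    normal approximation with tie correction. Returns ``(U, p)`` where U is
    the statistic for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0

    if n1 + n2 <= 12:
        center = n1 * n2 / 2.0
        dev_obs = abs(u_obs - center)
        hits = 0
        total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - center) >= dev_obs - 1e-9:
                hits += 1
        return float(u_obs), hits / total

    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return float(u_obs), 1.0
    z = (u_obs - n1 * n2 / 2.0) / math.sqrt(var_u)
    return float(u_obs), float(2.0 * sps.norm.sf(abs(z)))


def chi_squared_test(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r x c count table."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = sps.chi2_contingency(tab, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def pearson_corr_permutation(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Pearson correlation with a two-sided permutation p-value.

    ``p = (1 + #{permutations with |r*| >= |r|}) / (n_perm + 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    denom_x = math.sqrt((xc**2).sum())
    hits = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        yc = yp - yp.mean()
        r_perm = (xc * yc).sum() / (denom_x * math.sqrt((yc**2).sum()))
        if abs(r_perm) >= abs(r):
            hits += 1
    return r, (1 + hits) / (n_perm + 1)
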