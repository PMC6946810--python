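"""Stage 5: LD scores, heritability, genetic correlation, partitioning.

LD-score regression exploits the linear relationship between a
variant's association chi-square and its LD score (the summed r^2 with
its neighbours): under a polygenic model

    E[chi2_j] = 1 + N h2 l_j / M  (+ confounding in the intercept),

so the slope of chi2 on l recovers the SNP heritability h2, and the
slope of z1*z2 on l recovers the genetic covariance between two traits.
Standard errors come from a delete-one block jackknife over contiguous
variant blocks (20 by default at this scale).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    GeneticCorrelation,
    GenotypePanel,
    HeritabilityEstimate,
    LDScoreTable,
    PartitionReport,
)

PARTITION_BONFERRONI_P = 8.5e-4


def compute_ld_scores(
    panel: GenotypePanel,
    window_kb: float = 1_000.0,
    exclude_regions: list[tuple[int, int, int]] | None = None,
) -> LDScoreTable:
    """Per-variant LD scores with the small-sample bias adjustment.

    ``l_j = 1 + sum over neighbours within the window of
    max(0, r^2 - (1 - r^2)/(n - 2))``; the self correlation contributes
    the leading 1.  ``exclude_regions`` is a list of (chrom, start, end)
    intervals (e.g. an MHC-style mask) whose variants get NaN scores.
    """
    n = panel.n_individuals
    if n < 3:
        raise ValueError("need at least three individuals for adjusted r^2")
    if window_kb < 0:
        raise ValueError("window must be non-negative")
    window_bp = window_kb * 1000.0

    # standardize dosages once; columns with zero variance never correlate
    g = panel.dosages
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    g = g / sd_safe

    m = panel.n_variants
    l2 = np.ones(m)
    masked = np.zeros(m, dtype=bool)
    if exclude_regions:
        for chrom, start, end in exclude_regions:
            masked |= (panel.chrom == chrom) & (panel.pos >= start) & (panel.pos <= end)

    for j in range(m):
        near = (
            (panel.chrom == panel.chrom[j])
            & (np.abs(panel.pos - panel.pos[j]) <= window_bp)
        )
        near[j] = False
        idx = np.flatnonzero(near & (sd > 0))
        if idx.size == 0 or sd[j] == 0:
            continue
        r = (g[:, idx].T @ g[:, j]) / n
        r2 = r**2
        r2_adj = np.maximum(r2 - (1 - r2) / (n - 2), 0.0)
        l2[j] += float(r2_adj.sum())
    l2[masked] = np.nan
    return LDScoreTable(snp=panel.variant_ids.copy(), l2=l2, window_kb=window_kb)


def _block_bounds(m: int, n_blocks: int) -> list[np.ndarray]:
    return [np.asarray(b) for b in np.array_split(np.arange(m), n_blocks)]


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray, intercept: float | None = None):
    """Weighted least squares of y on x; returns (slope, intercept).

    ``intercept`` pins the intercept when not None.
    """
    if intercept is not None:
        yc = y - intercept
        slope = float(np.sum(w * x * yc) / np.sum(w * x**2))
        return slope, intercept
    sw = np.sum(w)
    mx = np.sum(w * x) / sw
    my = np.sum(w * y) / sw
    slope = float(np.sum(w * (x - mx) * (y - my)) / np.sum(w * (x - mx) ** 2))
    return slope, float(my - slope * mx)


def estimate_h2(
    z: np.ndarray,
    n_samples: float,
    ld_scores: np.ndarray,
    m_total: int | None = None,
    n_blocks: int = 20,
    constrain_intercept: float | None = None,
) -> HeritabilityEstimate:
    """SNP heritability from the regression of chi-square on LD score.

    Two-step weights: an unweighted first pass gives a provisional h2,
    then the final pass weights each variant by
    ``1 / (l_j * (1 + N h2_0 l_j / M)^2)`` (heteroskedasticity and
    over-counting of correlated variants).  ``slope * M / N`` is h2.
    The intercept is free by default (absorbing confounding inflation);
    pass ``constrain_intercept=1.0`` to pin it.
    """
    z = np.asarray(z, dtype=float)
    ell = np.asarray(ld_scores, dtype=float)
    keep = np.isfinite(ell) & np.isfinite(z)
    z, ell = z[keep], ell[keep]
    m = z.size
    if m != ell.size:
        raise ValueError("z and LD scores must align")
    if m < n_blocks:
        raise ValueError("fewer variants than jackknife blocks")
    if n_samples <= 1:
        raise ValueError("N must exceed 1")
    m_total = m if m_total is None else m_total

    chi2 = z**2

    def fit(idx) -> tuple[float, float]:
        x, y = ell[idx], chi2[idx]
        slope0, icpt0 = _wls(x, y, np.ones(x.size), constrain_intercept)
        h2_0 = np.clip(slope0 * m_total / n_samples, 0.0, 1.0)
        w = 1.0 / (np.maximum(x, 1.0) * (1 + n_samples * h2_0 * x / m_total) ** 2)
        slope, icpt = _wls(x, y, w, constrain_intercept)
        return slope * m_total / n_samples, icpt

    all_idx = np.arange(m)
    h2_hat, intercept = fit(all_idx)

    blocks = _block_bounds(m, n_blocks)
    jk = np.array([fit(np.setdiff1d(all_idx, b, assume_unique=True)) for b in blocks])
    h2_se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((jk[:, 0] - jk[:, 0].mean()) ** 2)))
    icpt_se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((jk[:, 1] - jk[:, 1].mean()) ** 2)))

    return HeritabilityEstimate(
        h2=float(h2_hat),
        se=h2_se,
        intercept=float(intercept),
        intercept_se=icpt_se,
        m_variants=m_total,
        n_samples=n_samples,
        mean_chi2=float(chi2.mean()),
        n_blocks=n_blocks,
    )


def estimate_rg(
    z1: np.ndarray,
    z2: np.ndarray,
    n1: float,
    n2: float,
    ld_scores: np.ndarray,
    m_total: int | None = None,
    n_blocks: int = 20,
    impairment_rescale: bool = False,
) -> GeneticCorrelation:
    """Cross-trait LD-score regression.

    The slope of ``z1*z2`` on the LD score times ``M / sqrt(N1 N2)`` is
    the genetic covariance rho_g; dividing by the square root of the two
    heritabilities gives r_g.  The free intercept absorbs sample
    overlap.  The jackknife recomputes all three regressions per
    deleted block.  ``impairment_rescale`` flips the sign, restating the
    correlation with respect to *impaired* (reduced) function; reported
    r_g outside [-1, 1] is clamped to +/-1.25 with a warning.
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    ell = np.asarray(ld_scores, float)
    keep = np.isfinite(ell)
    z1, z2, ell = z1[keep], z2[keep], ell[keep]
    m = ell.size
    m_total = m if m_total is None else m_total
    if m < n_blocks:
        raise ValueError("fewer variants than jackknife blocks")

    prod = z1 * z2
    chi1, chi2_ = z1**2, z2**2

    def fit(idx) -> tuple[float, float, float, float]:
        x = ell[idx]
        w = 1.0 / np.maximum(x, 1.0)
        s1, _ = _wls(x, chi1[idx], w)
        s2, _ = _wls(x, chi2_[idx], w)
        sc, icpt = _wls(x, prod[idx], w)
        h2_1 = s1 * m_total / n1
        h2_2 = s2 * m_total / n2
        rho = sc * m_total / np.sqrt(n1 * n2)
        if h2_1 <= 0 or h2_2 <= 0:
            return rho, np.nan, icpt, np.nan
        return rho, rho / np.sqrt(h2_1 * h2_2), icpt, h2_1 * h2_2

    all_idx = np.arange(m)
    rho_g, rg, icpt, _ = fit(all_idx)
    if not np.isfinite(rg):
        raise ValueError(
            "h2 estimate non-positive for at least one trait; r_g undefined"
        )

    blocks = _block_bounds(m, n_blocks)
    jk = np.array([fit(np.setdiff1d(all_idx, b, assume_unique=True))[1] for b in blocks])
    jk = jk[np.isfinite(jk)]
    nb = jk.size
    se = float(np.sqrt((nb - 1) / nb * np.sum((jk - jk.mean()) ** 2))) if nb > 1 else float("nan")

    if impairment_rescale:
        rho_g, rg = -rho_g, -rg
    if abs(rg) > 1:
        import warnings

        warnings.warn(f"r_g = {rg:.3f} outside [-1, 1]; clamped", stacklevel=2)
        rg = float(np.clip(rg, -1.25, 1.25))

    p = 2 * stats.norm.sf(abs(rg) / se) if se > 0 else 0.0
    # recover component h2s for reporting
    h1 = estimate_h2(z1, n1, ell, m_total, n_blocks)
    h2e = estimate_h2(z2, n2, ell, m_total, n_blocks)
    return GeneticCorrelation(
        rho_g=float(rho_g),
        rg=float(rg),
        se=se,
        p=float(p),
        cross_intercept=float(icpt),
        h2_1=h1.h2,
        h2_2=h2e.h2,
    )


def partition_h2(
    z: np.ndarray,
    n_samples: float,
    partitioned_ld: np.ndarray,
    annotations: np.ndarray,
    m_total: int | None = None,
    n_blocks: int = 20,
    bonferroni_p: float = PARTITION_BONFERRONI_P,
) -> PartitionReport:
    """Stratified heritability over user-supplied annotations.

    Fits ``E[chi2_j] = N * sum_c tau_c * l(j,c) + intercept`` by weighted
    multiple regression; for binary annotation c,
    ``h2_c = sum_{j in c} sum_c' tau_c' a(j,c')`` and enrichment is the
    proportion of heritability over the proportion of SNPs.  Enrichment
    p-values come from a block jackknife on (enrichment - 1); the
    significance flag applies the Bonferroni threshold (default
    8.5e-4).
    """
    z = np.asarray(z, float)
    L = np.asarray(partitioned_ld, float)  # m x C
    A = np.asarray(annotations, float)  # m x C
    m, n_annot = L.shape
    if A.shape != L.shape:
        raise ValueError("annotation matrix must match partitioned LD scores")
    m_total = m if m_total is None else m_total

    if np.linalg.matrix_rank(L) < n_annot:
        raise ValueError("singular annotation design")

    chi2 = z**2
    ell_tot = L.sum(axis=1)
    w = 1.0 / np.maximum(ell_tot, 1.0)

    def fit(idx):
        X = np.column_stack([np.ones(idx.size), n_samples * L[idx]])
        Wx = w[idx][:, None] * X
        coef, *_ = np.linalg.lstsq(X.T @ Wx, Wx.T @ chi2[idx], rcond=None)
        tau = coef[1:]
        per_snp_h2 = A @ tau  # expected h2 contribution of each variant
        h2_tot = float(per_snp_h2.sum())
        h2_c = A.T @ per_snp_h2  # for binary annotations: sum over members
        prop_h2 = h2_c / h2_tot if h2_tot != 0 else np.full(n_annot, np.nan)
        return tau, prop_h2, h2_tot

    all_idx = np.arange(m)
    tau, prop_h2, h2_tot = fit(all_idx)
    m_c = A.sum(axis=0)
    prop_snps = m_c / m
    enrichment = prop_h2 / prop_snps

    blocks = _block_bounds(m, n_blocks)
    jk_prop = np.array(
        [fit(np.setdiff1d(all_idx, b, assume_unique=True))[1] for b in blocks]
    )
    nb = len(blocks)
    prop_se = np.sqrt((nb - 1) / nb * np.sum((jk_prop - jk_prop.mean(axis=0)) ** 2, axis=0))
    jk_enr = jk_prop / prop_snps
    enr_se = np.sqrt((nb - 1) / nb * np.sum((jk_enr - jk_enr.mean(axis=0)) ** 2, axis=0))

    with np.errstate(divide="ignore", invalid="ignore"):
        z_enr = np.where(enr_se > 0, (enrichment - 1) / enr_se, np.inf)
    p_enr = 2 * stats.norm.sf(np.abs(z_enr))
    # a single all-SNPs annotation is exactly unenriched, never "significant"
    p_enr = np.where(np.isclose(enrichment, 1.0) & (enr_se == 0), 1.0, p_enr)

    table = pd.DataFrame(
        {
            "annotation": [f"annot_{c}" for c in range(n_annot)],
            "tau": tau,
            "prop_h2": prop_h2,
            "prop_h2_se": prop_se,
            "prop_snps": prop_snps,
            "enrichment": enrichment,
            "enrichment_se": enr_se,
            "p": p_enr,
            "significant": p_enr < bonferroni_p,
        }
    )
    return PartitionReport(table=table, h2_total=h2_tot * m_total / m if m else 0.0,
                           bonferroni_alpha=bonferroni_p)
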