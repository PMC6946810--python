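"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline is exercised on data produced
here: genotype dosage panels with block LD, disjoint exposure/outcome
cohorts for two-sample MR, direct summary-level instrument sets for
estimator unit tests, spirometry blow series, and paired polygenic
z-score vectors for LD-score regression.

All generators are pure functions of (parameters, seed): the same seed
reproduces the same draws, and no global random state is touched.
Ground-truth labels (true causal effect, per-variant validity, true
heritabilities) are carried alongside the data for evaluation only —
no inference code reads them.

Design notes
------------
* LD is generated through a latent Gaussian copula: within a block the
  latent variables follow an AR(1) process with parameter ``rho``, and
  each of the two haplotypes per individual is thresholded at the
  allele-frequency quantile, which yields Hardy–Weinberg genotype
  frequencies with controllable dosage r².
* The binary outcome uses a logistic (log-odds) model rather than a
  liability threshold, so the true "odds ratio" ground truth is exact on
  the scale MR estimates it; the intercept is solved by bisection so the
  expected case fraction matches the target to ±0.001.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats

from .containers import BlowSeries, GenotypePanel, HarmonizedSet, SimulationScenario

# Blocks are placed further apart than one clumping window so LD-based
# operations never bridge blocks.
_BLOCK_GAP_BP = 20_000_000
_WITHIN_BLOCK_SPACING_BP = 2_000


def simulate_genotype_panel(
    n: int,
    m: int,
    block_size: int = 10,
    maf_range: tuple[float, float] = (0.05, 0.5),
    rho: float = 0.8,
    seed: int = 0,
) -> GenotypePanel:
    """Simulate a dosage panel with AR(1) latent LD inside fixed-size blocks.

    Parameters
    ----------
    n, m
        Individuals and variants.
    block_size
        Variants per LD block; the last block may be shorter.
    maf_range
        Minor-allele frequencies drawn uniformly from this interval,
        which must lie within (0, 0.5].
    rho
        Latent autoregressive correlation between adjacent variants in a
        block (|rho| < 1). The realized dosage correlation is somewhat
        attenuated by thresholding.
    """
    if n <= 0 or m <= 0 or block_size <= 0:
        raise ValueError("n, m and block_size must be positive")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")

    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=m)
    thresholds = stats.norm.ppf(maf)

    # Thresholding a latent Gaussian attenuates correlation, so the latent
    # AR coefficient for each adjacent pair is solved (inverse tetrachoric)
    # so that the *allele* correlation matches the requested rho; when the
    # allele frequencies differ too much for rho to be attainable, the
    # closest achievable correlation is used.
    block_id = np.arange(m) // block_size
    latent = np.zeros(m)  # latent AR coefficient linking variant k to k-1
    if rho != 0.0:
        for k in range(1, m):
            if block_id[k] == block_id[k - 1]:
                latent[k] = _latent_ar_coefficient(
                    thresholds[k - 1], thresholds[k], maf[k - 1], maf[k], rho
                )

    dosages = np.empty((n, m), dtype=float)
    for b in np.unique(block_id):
        cols = np.flatnonzero(block_id == b)
        size = cols.size
        hap_sum = np.zeros((n, size))
        for _ in range(2):
            z = np.empty((n, size))
            z[:, 0] = rng.standard_normal(n)
            if size > 1:
                eps = rng.standard_normal((n, size - 1))
                for k in range(1, size):
                    r = latent[cols[k]]
                    z[:, k] = r * z[:, k - 1] + np.sqrt(1 - r**2) * eps[:, k - 1]
            hap_sum += (z < thresholds[cols]).astype(float)
        dosages[:, cols] = hap_sum

    n_blocks = int(block_id.max()) + 1
    chrom = (np.unique(block_id) % 22 + 1)[block_id]
    # positions restart per chromosome; each block sits well inside one
    # 10,000 kb window and >10,000 kb away from the next block on the
    # same chromosome
    block_rank_on_chrom = np.unique(block_id) // 22
    pos = (
        1
        + block_rank_on_chrom[block_id] * _BLOCK_GAP_BP
        + (np.arange(m) % block_size) * _WITHIN_BLOCK_SPACING_BP
    )

    alleles = np.array(["A", "C", "G", "T"])
    eff = rng.integers(0, 4, size=m)
    oth = (eff + rng.integers(1, 4, size=m)) % 4

    return GenotypePanel(
        variant_ids=np.array([f"rs{i}" for i in range(m)]),
        chrom=chrom.astype(int),
        pos=pos.astype(int),
        effect_allele=alleles[eff],
        other_allele=alleles[oth],
        dosages=dosages,
        block_id=block_id,
    )


def _latent_ar_coefficient(t1: float, t2: float, p1: float, p2: float,
                           target: float) -> float:
    """Latent Gaussian correlation giving allele correlation ``target``.

    The allele indicators are 1{z < t}; their correlation under latent
    correlation r is ``(Phi2(t1, t2; r) - p1 p2) / sqrt(p1 q1 p2 q2)``.
    Solved by bisection; targets beyond the attainable range (unequal
    frequencies bound the correlation away from 1) return the boundary.
    """
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def allele_corr(r: float) -> float:
        cov = [[1.0, r], [r, 1.0]]
        p11 = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([t1, t2])
        return (p11 - p1 * p2) / denom

    limit = 0.9999
    if target >= allele_corr(limit):
        return limit
    if target <= allele_corr(-limit):
        return -limit
    return float(optimize.brentq(lambda r: allele_corr(r) - target,
                                 -limit, limit, xtol=1e-6))


def split_panel(panel: GenotypePanel, n_first: int) -> tuple[GenotypePanel, GenotypePanel]:
    """Split a panel's individuals into two disjoint panels sharing the
    variant map — the standard way to realize a two-sample design."""
    if not 0 < n_first < panel.n_individuals:
        raise ValueError("n_first must split the panel non-trivially")
    import dataclasses

    first = dataclasses.replace(panel, dosages=panel.dosages[:n_first])
    second = dataclasses.replace(panel, dosages=panel.dosages[n_first:])
    return first, second


def _solve_logistic_intercept(eta: np.ndarray, k_target: float, tol: float = 1e-3) -> float:
    """Intercept b0 such that mean(sigmoid(b0 + eta)) = k_target (bisection)."""

    def gap(b0: float) -> float:
        return float(special.expit(b0 + eta).mean() - k_target)

    lo, hi = -30.0, 30.0
    return float(optimize.bisect(gap, lo, hi, xtol=tol / 10))


def simulate_mr_cohorts(
    panel_exposure: GenotypePanel,
    panel_outcome: GenotypePanel,
    scenario: SimulationScenario,
):
    """Generate disjoint exposure and outcome samples for two-sample MR.

    The exposure is ``genetic score + confounder + noise`` standardized to
    unit variance with the genetic share fixed at ``h2_exposure``.  The
    outcome sample's (unobserved) exposure follows the same model;
    case/control status comes from a logistic model whose intercept is
    solved so the expected case fraction equals ``case_fraction``.
    Invalid instruments receive direct log-odds effects (mean
    ``alpha_mean``; zero-mean when ``balanced``).

    Returns
    -------
    dict with keys ``exposure`` (float vector, exposure panel),
    ``outcome`` (0/1 vector, outcome panel), and ``truth``
    (causal index, per-variant betas and pleiotropic alphas, theta).
    """
    scenario.validate()
    if panel_exposure.n_variants != panel_outcome.n_variants:
        raise ValueError("panels must share the variant map")
    if not np.array_equal(panel_exposure.variant_ids, panel_outcome.variant_ids):
        raise ValueError("panels must share the variant map")

    rng = np.random.default_rng(scenario.seed)
    m = panel_exposure.n_variants
    causal = rng.choice(m, size=scenario.n_causal, replace=False)
    causal.sort()
    beta = np.zeros(m)
    beta[causal] = rng.standard_normal(scenario.n_causal)

    def genetic_score(panel: GenotypePanel) -> np.ndarray:
        g = panel.dosages[:, causal] - panel.dosages[:, causal].mean(axis=0)
        return g @ beta[causal]

    # scale betas so Var(score) = h2 in the exposure sample
    score_x = genetic_score(panel_exposure)
    sd = score_x.std()
    if sd > 0 and scenario.h2_exposure > 0:
        scale = np.sqrt(scenario.h2_exposure) / sd
    else:
        scale = 0.0
    beta *= scale
    score_x *= scale

    cx, cy = scenario.confounder_on_exposure, scenario.confounder_on_outcome
    resid_var = 1.0 - scenario.h2_exposure - cx**2
    if resid_var < 0:
        raise ValueError("h2_exposure + confounder_on_exposure^2 exceeds 1")

    u_x = rng.standard_normal(panel_exposure.n_individuals)
    exposure = score_x + cx * u_x + np.sqrt(resid_var) * rng.standard_normal(
        panel_exposure.n_individuals
    )

    # pleiotropy: a subset of causal variants also hits the outcome directly
    n_invalid = int(round(scenario.fraction_invalid * scenario.n_causal))
    invalid = rng.choice(causal, size=n_invalid, replace=False) if n_invalid else np.array([], int)
    alpha = np.zeros(m)
    if n_invalid:
        mean = 0.0 if scenario.balanced else scenario.alpha_mean
        alpha[invalid] = rng.normal(mean, scenario.alpha_sd, size=n_invalid)

    score_y = genetic_score(panel_outcome)
    u_y = rng.standard_normal(panel_outcome.n_individuals)
    latent_exposure = score_y + cx * u_y + np.sqrt(resid_var) * rng.standard_normal(
        panel_outcome.n_individuals
    )
    g_out = panel_outcome.dosages - panel_outcome.dosages.mean(axis=0)
    eta = scenario.theta * latent_exposure + cy * u_y + g_out @ alpha
    b0 = _solve_logistic_intercept(eta, scenario.case_fraction)
    outcome = (rng.uniform(size=eta.size) < special.expit(b0 + eta)).astype(int)

    truth = {
        "causal_index": causal,
        "invalid_index": invalid,
        "beta": beta,
        "alpha": alpha,
        "theta": scenario.theta,
        "intercept": b0,
    }
    return {"exposure": exposure, "outcome": outcome, "truth": truth}


def simulate_summary_mr(
    n_instruments: int,
    theta: float,
    beta_exp_mean: float = 0.1,
    beta_exp_sd: float = 0.03,
    se_exp: float = 0.01,
    se_out: float = 0.05,
    fraction_invalid: float = 0.0,
    alpha_mean: float = 0.0,
    alpha_sd: float = 0.0,
    balanced: bool = True,
    seed: int = 0,
) -> HarmonizedSet:
    """Directly simulate a harmonized summary-level instrument set.

    ``beta_exp_hat ~ N(beta_exp, se_exp^2)`` and
    ``beta_out_hat ~ N(theta * beta_exp + alpha_j, se_out^2)`` with the
    pleiotropic ``alpha_j`` nonzero for a ``fraction_invalid`` subset
    (zero-mean when ``balanced``).  True exposure effects are
    ``|N(beta_exp_mean, beta_exp_sd^2)|`` so that instruments stay
    oriented toward one direction of effect, mimicking a set aligned to
    the exposure-increasing allele.
    """
    if n_instruments < 1:
        raise ValueError("need at least one instrument")
    if se_exp < 0 or se_out < 0:
        raise ValueError("standard errors must be non-negative")

    rng = np.random.default_rng(seed)
    beta_exp = np.abs(rng.normal(beta_exp_mean, beta_exp_sd, size=n_instruments))
    beta_exp = np.maximum(beta_exp, 1e-3)

    n_invalid = int(round(fraction_invalid * n_instruments))
    alpha = np.zeros(n_instruments)
    if n_invalid:
        which = rng.choice(n_instruments, size=n_invalid, replace=False)
        mean = 0.0 if balanced else alpha_mean
        alpha[which] = rng.normal(mean, alpha_sd, size=n_invalid)
    elif not balanced and alpha_mean != 0.0:
        # directional pleiotropy on every instrument when no explicit
        # invalid fraction is given
        alpha[:] = rng.normal(alpha_mean, alpha_sd, size=n_instruments)

    beta_exp_hat = beta_exp + se_exp * rng.standard_normal(n_instruments)
    beta_out_hat = theta * beta_exp + alpha + se_out * rng.standard_normal(n_instruments)

    hset = HarmonizedSet.from_arrays(
        beta_exp_hat,
        np.full(n_instruments, max(se_exp, 1e-12)),
        beta_out_hat,
        np.full(n_instruments, max(se_out, 1e-12)),
        truth={
            "theta": theta,
            "beta_exp": beta_exp,
            "alpha": alpha,
            "invalid": alpha != 0.0,
        },
    )
    return hset


def simulate_blows(
    n: int,
    one_blow_fraction: float = 0.02,
    discordant_fraction: float = 0.08,
    n_blows: int = 3,
    noise: float = 0.05,
    seed: int = 0,
) -> list[BlowSeries]:
    """Spirometry blow series with configurable QC-failure fractions.

    ``one_blow_fraction`` of individuals complete a single blow (always
    excluded by QC); ``discordant_fraction`` have every non-best blow
    differing from the best by more than 0.15 L (also excluded).  The
    remainder have reproducible blows within ``noise`` litres.
    """
    if noise < 0:
        raise ValueError("noise must be non-negative")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    series = []
    for i in range(n):
        base_fev1 = rng.uniform(1.5, 4.5)
        base_fvc = base_fev1 / rng.uniform(0.55, 0.95)
        if u[i] < one_blow_fraction:
            fev1 = np.array([base_fev1])
            fvc = np.array([base_fvc])
        elif u[i] < one_blow_fraction + discordant_fraction:
            # all non-best blows > 0.15 L below the best
            drops = rng.uniform(0.2, 0.6, size=n_blows - 1)
            fev1 = np.concatenate([[base_fev1], base_fev1 - drops])
            fvc = np.concatenate([[base_fvc], base_fvc - drops])
        else:
            jitter = rng.uniform(0, min(noise, 0.14), size=n_blows - 1)
            fev1 = np.concatenate([[base_fev1], base_fev1 - jitter])
            fvc = np.concatenate([[base_fvc], base_fvc - jitter])
        series.append(BlowSeries(individual_id=f"id{i}", fev1=fev1, fvc=fvc))
    return series


def simulate_polygenic_pair(
    n1: int,
    n2: int,
    m: int,
    h2_1: float,
    h2_2: float,
    rg: float,
    sample_overlap: int = 0,
    pheno_corr: float | None = None,
    seed: int = 0,
):
    """Paired GWAS z-scores under the LD-score-regression generative model.

    Per-variant z-scores are drawn from a bivariate normal with

    ``Var(z_i) = 1 + N_i * h2_i * l_j / M`` and
    ``Cov = sqrt(N1 N2) * rho_g * l_j / M + overlap * r_p / sqrt(N1 N2)``

    where ``rho_g = rg * sqrt(h2_1 h2_2)``, ``l_j`` are synthetic LD
    scores (1 + Gamma-distributed), and the overlap term reproduces the
    cross-trait intercept induced by shared samples with phenotypic
    correlation ``r_p`` (defaults to ``rg``).

    Returns dict with ``z1``, ``z2``, ``ld_scores`` and ``truth``.
    """
    if not (0 <= h2_1 <= 1 and 0 <= h2_2 <= 1):
        raise ValueError("heritabilities must be in [0, 1]")
    if abs(rg) > 1:
        raise ValueError("|rg| must be <= 1")
    if sample_overlap > min(n1, n2):
        raise ValueError("overlap cannot exceed either sample size")

    rng = np.random.default_rng(seed)
    ell = 1.0 + rng.gamma(shape=2.0, scale=2.0, size=m)
    rho_g = rg * np.sqrt(h2_1 * h2_2)
    r_p = rg if pheno_corr is None else pheno_corr

    var1 = 1.0 + n1 * h2_1 * ell / m
    var2 = 1.0 + n2 * h2_2 * ell / m
    cov = np.sqrt(n1 * n2) * rho_g * ell / m + sample_overlap * r_p / np.sqrt(n1 * n2)
    # guard: keep correlation valid
    cov = np.clip(cov, -0.999 * np.sqrt(var1 * var2), 0.999 * np.sqrt(var1 * var2))

    e1 = rng.standard_normal(m)
    e2 = rng.standard_normal(m)
    z1 = np.sqrt(var1) * e1
    b = cov / np.sqrt(var1)  # regression of z2 on z1
    resid_sd = np.sqrt(np.maximum(var2 - b**2, 1e-12))
    z2 = b * e1 + resid_sd * e2

    truth = {"h2_1": h2_1, "h2_2": h2_2, "rg": rg, "rho_g": rho_g, "m": m}
    return {"z1": z1, "z2": z2, "ld_scores": ell, "truth": truth}
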