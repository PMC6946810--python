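"""Stage 4: heterogeneity, pleiotropy, directionality, screening, power.

The central statistic is Cochran's Q with modified second-order weights:
per-variant ratio estimates ``theta_j = by/bx`` weighted by

    w_j(theta)^-1 = sy_j^2/bx_j^2 + theta^2 sx_j^2/bx_j^2,

with the weights and the minimizing causal effect iterated to a fixed
point.  Large per-variant contributions identify outlier instruments
suspected of horizontal pleiotropy; the default removal rule is
iterative with a Bonferroni-corrected chi-square(1) cutoff, a
deliberately conservative systematic choice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import (
    HarmonizedSet,
    HeterogeneityReport,
    NomeReport,
    PowerSpec,
    SteigerReport,
)


def _modified_weights(bx, sx, sy, theta):
    return 1.0 / (sy**2 / bx**2 + theta**2 * sx**2 / bx**2)


def cochran_q_modified(
    hset: HarmonizedSet,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> HeterogeneityReport:
    """Cochran's Q with modified second-order weights.

    Starting from the first-order IVW estimate, the weight update and
    weighted-mean minimization are iterated until the causal effect
    moves by less than ``tol``; the fixed point is the minimizer of
    Q(theta).  The p-value is from chi-square with J-1 df.  Per-variant
    contributions Q_j sum to Q; flags mark contributions exceeding the
    Bonferroni chi-square(1) quantile at alpha = 0.05/J.
    """
    bx, sx, by, sy = hset.arrays()
    j = bx.size
    if j < 2:
        raise ValueError("heterogeneity needs at least two instruments")
    ratios = by / bx

    def q_of(theta: float) -> float:
        w = _modified_weights(bx, sx, sy, theta)
        return float(np.sum(w * (ratios - theta) ** 2))

    # weight-update / weighted-mean iteration from the first-order IVW start
    theta = float(np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2))
    for _ in range(max_iter):
        w = _modified_weights(bx, sx, sy, theta)
        theta_new = float(np.sum(w * ratios) / np.sum(w))
        if abs(theta_new - theta) < tol:
            theta = theta_new
            break
        theta = theta_new
    else:
        raise RuntimeError("modified-weight Q iteration did not converge")

    # polish to the exact minimizer of Q(theta): the weights themselves
    # depend on theta, so the fixed point is only a close starting value
    span = max(np.ptp(ratios), 1e-3)
    res = optimize.minimize_scalar(
        q_of, bounds=(theta - span, theta + span), method="bounded",
        options={"xatol": 1e-10},
    )
    if res.fun <= q_of(theta):
        theta = float(res.x)

    w = _modified_weights(bx, sx, sy, theta)
    qj = w * (ratios - theta) ** 2
    q = float(qj.sum())
    p = float(stats.chi2.sf(q, j - 1))
    cutoff = stats.chi2.ppf(1 - 0.05 / j, 1)
    return HeterogeneityReport(
        q=q,
        df=j - 1,
        p=p,
        q_contributions=qj,
        outlier_flags=qj > cutoff,
        theta_min=theta,
        phi=q / (j - 1),
        snp=hset.table["SNP"].to_numpy(),
    )


def filter_outliers(
    hset: HarmonizedSet,
    q_alpha: float | None = None,
    min_instruments: int = 3,
) -> tuple[HarmonizedSet, pd.DataFrame]:
    """Iteratively remove the largest Q contributor while it exceeds the
    Bonferroni chi-square(1) cutoff (alpha = 0.05/J by default).

    Q and its minimizer are recomputed after every removal; iteration
    stops when no contribution exceeds the cutoff or when another
    removal would leave fewer than ``min_instruments``.  Returns the
    filtered set and a removal log (SNP, Q contribution, round).
    """
    current = hset
    removals = []
    round_no = 0
    while current.n_instruments > min_instruments:
        report = cochran_q_modified(current)
        j = current.n_instruments
        alpha = (0.05 / j) if q_alpha is None else q_alpha
        cutoff = stats.chi2.ppf(1 - alpha, 1)
        worst = int(np.argmax(report.q_contributions))
        if report.q_contributions[worst] <= cutoff:
            break
        round_no += 1
        snp = current.table.iloc[worst]["SNP"]
        removals.append((snp, float(report.q_contributions[worst]), round_no))
        table = current.table.drop(current.table.index[worst]).reset_index(drop=True)
        current = HarmonizedSet(
            table=table,
            exposure_name=current.exposure_name,
            outcome_name=current.outcome_name,
            scale=current.scale,
            impairment_oriented=current.impairment_oriented,
            exclusions=current.exclusions,
            truth=current.truth,
        )
    log = pd.DataFrame(removals, columns=["SNP", "q_contribution", "round"])
    return current, log


def i2_gx(hset: HarmonizedSet) -> NomeReport:
    """Instrument-precision statistic for the no-measurement-error
    assumption behind MR-Egger.

    ``Q_GX`` is the heterogeneity of the exposure effects about their
    inverse-variance-weighted mean; ``I2_GX = max(0, (Q_GX - (J-1))/Q_GX)``.
    Values near 1 mean exposure effects are precisely estimated; below
    0.90 indicates regression-dilution bias in the Egger intercept test.
    """
    bx, sx, _, _ = hset.arrays()
    j = bx.size
    if j < 2:
        raise ValueError("I2_GX needs at least two instruments")
    w = 1 / sx**2
    mean_w = np.sum(w * bx) / np.sum(w)
    q_gx = float(np.sum((bx - mean_w) ** 2 / sx**2))
    i2 = max(0.0, (q_gx - (j - 1)) / q_gx) if q_gx > 0 else 0.0
    return NomeReport(i2_gx=float(i2), q_gx=q_gx, df=j - 1)


def steiger(
    hset: HarmonizedSet,
    n_exposure: int,
    n_outcome: int,
    z_threshold: float = 1.96,
) -> SteigerReport:
    """Directionality test: does the instrument set explain more variance
    in the exposure than in the outcome?

    Per-variant ``r2 = z^2 / (z^2 + N - 2)`` on the observed scale (for
    the binary outcome this is a documented approximation; no
    liability-scale conversion is applied).  The aggregate comparison
    uses a Fisher-z difference with effective N the harmonic mean of the
    two sample sizes.  Variants individually explaining more outcome
    than exposure variance are listed as failing.
    """
    if n_exposure <= 3 or n_outcome <= 3:
        raise ValueError("sample sizes must exceed 3")
    bx, sx, by, sy = hset.arrays()
    zx = bx / sx
    zy = by / sy
    r2x = zx**2 / (zx**2 + n_exposure - 2)
    r2y = zy**2 / (zy**2 + n_outcome - 2)

    rx = np.sqrt(min(float(r2x.sum()), 0.999999))
    ry = np.sqrt(min(float(r2y.sum()), 0.999999))
    n_eff = 2 * n_exposure * n_outcome / (n_exposure + n_outcome)
    se = np.sqrt(2.0 / (n_eff - 3))
    z = (np.arctanh(rx) - np.arctanh(ry)) / se
    p = 2 * stats.norm.sf(abs(z))
    return SteigerReport(
        r2_exposure=r2x,
        r2_outcome=r2y,
        direction_exposure_to_outcome=bool(r2x.sum() > r2y.sum()),
        z=float(z),
        p=float(p),
        indeterminate=bool(abs(z) < z_threshold),
        failing_variants=hset.table["SNP"].to_numpy()[r2y > r2x],
    )


def steiger_filter(hset: HarmonizedSet, n_exposure: int, n_outcome: int) -> HarmonizedSet:
    """Remove variants explaining more outcome than exposure variance."""
    report = steiger(hset, n_exposure, n_outcome)
    failing = set(report.failing_variants)
    table = hset.table[~hset.table["SNP"].isin(failing)].reset_index(drop=True)
    return HarmonizedSet(
        table=table,
        exposure_name=hset.exposure_name,
        outcome_name=hset.outcome_name,
        scale=hset.scale,
        impairment_oriented=hset.impairment_oriented,
        exclusions=hset.exclusions,
        truth=hset.truth,
    )


def confounder_screen(
    instrument_ids,
    confounder_tables: dict[str, pd.DataFrame],
    thresholds: tuple[float, float] = (5e-8, 1e-5),
) -> pd.DataFrame:
    """Flag instruments associated with candidate confounders.

    For each confounder scan, variants are flagged at each threshold;
    variants missing from a table are recorded as unscreened rather than
    silently passed.  Returns a long frame (SNP, confounder, p, flag_5e-8,
    flag_1e-5, screened).
    """
    strict, loose = sorted(thresholds)
    rows = []
    for name, table in confounder_tables.items():
        lookup = table.set_index("SNP")["P"]
        for snp in instrument_ids:
            if snp in lookup.index:
                p = float(lookup.loc[snp])
                rows.append((snp, name, p, p < strict, p < loose, True))
            else:
                rows.append((snp, name, np.nan, False, False, False))
    return pd.DataFrame(
        rows,
        columns=["SNP", "confounder", "P",
                 f"flag_{strict:g}", f"flag_{loose:g}", "screened"],
    )


def remove_flagged(
    hset: HarmonizedSet, screen: pd.DataFrame, flag_column: str
) -> HarmonizedSet:
    """Re-emit a harmonized set without confounder-flagged variants."""
    flagged = set(screen.loc[screen[flag_column], "SNP"])
    table = hset.table[~hset.table["SNP"].isin(flagged)].reset_index(drop=True)
    return HarmonizedSet(
        table=table,
        exposure_name=hset.exposure_name,
        outcome_name=hset.outcome_name,
        scale=hset.scale,
        impairment_oriented=hset.impairment_oriented,
        exclusions=hset.exclusions,
        truth=hset.truth,
    )


def power_binary(spec: PowerSpec) -> float:
    """Two-sample MR power for a binary outcome (noncentrality approximation).

    ``power = Phi(sqrt(N R^2 K (1-K)) |log OR| - z_{1-alpha/2})``.
    """
    spec.validate()
    ncp = np.sqrt(spec.n_total * spec.r_squared * spec.case_fraction *
                  (1 - spec.case_fraction)) * abs(np.log(spec.odds_ratio))
    z_crit = stats.norm.ppf(1 - spec.alpha / 2)
    return float(stats.norm.cdf(ncp - z_crit))


def minimum_detectable_or(
    n_total: int,
    case_fraction: float,
    r_squared: float,
    target_power: float = 0.80,
    alpha: float = 0.05,
) -> float:
    """Smallest OR > 1 detectable at the target power (bisection on log OR)."""
    if target_power <= alpha / 2:
        raise ValueError("target power must exceed alpha/2")

    def gap(log_or: float) -> float:
        spec = PowerSpec(n_total, case_fraction, r_squared, float(np.exp(log_or)), alpha)
        return power_binary(spec) - target_power

    lo, hi = 1e-8, 0.1
    while gap(hi) < 0:
        hi *= 2
        if hi > 50:
            raise ValueError("target power unreachable at this sample size")
    return float(np.exp(optimize.brentq(gap, lo, hi, xtol=1e-10)))
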