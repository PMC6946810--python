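"""Stage 1: phenotype QC, association scan, and instrument development.

Covers spirometry blow QC (0.15 L reproducibility rule), phenotype
derivation (z-scored FEV1/FVC volumes, the untransformed FEV1/FVC ratio,
COPD flag at ratio < 0.70), variant QC (Hardy–Weinberg exact test,
call rate, MAF), a per-variant linear association scan, greedy LD
clumping (r^2 < 0.05 within 10,000 kb), two-stage instrument selection
(discovery P < 5e-8, replication P < 0.05 with consistent direction),
and instrument-strength metrics (per-variant r^2, total R^2, F).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import (
    BlowSeries,
    GenotypePanel,
    InstrumentSet,
    SpirometryPhenotypes,
)

#: maximum difference (litres) between the best blow and a retained blow
BLOW_REPRODUCIBILITY_L = 0.15

#: chi-square(1) median, for the genomic-inflation factor
CHI2_1_MEDIAN = 0.454936423119572

COPD_RATIO_THRESHOLD = 0.70


# ---------------------------------------------------------------------------
# spirometry QC and phenotype derivation
# ---------------------------------------------------------------------------

def qc_blow(fev1: np.ndarray) -> tuple[bool, float]:
    """Apply the reproducibility rule to one series of blow volumes.

    The best measure is the maximum blow.  Individuals with a single blow
    are excluded (reproducibility cannot be assessed); non-best blows
    differing from the best by more than 0.15 L are dropped, and the
    individual passes only if at least one non-best blow remains.
    """
    fev1 = np.asarray(fev1, dtype=float)
    if fev1.size < 2:
        return False, float(fev1.max())
    best = float(fev1.max())
    others = np.delete(fev1, int(np.argmax(fev1)))
    retained = others[best - others <= BLOW_REPRODUCIBILITY_L]
    return retained.size >= 1, best


def qc_spirometry(series: list[BlowSeries]) -> pd.DataFrame:
    """Blow QC over a cohort; FEV1 and FVC must both be reproducible.

    Returns a frame with ``individual_id``, ``qc_pass``, ``best_fev1``,
    ``best_fvc``.
    """
    if not series:
        raise ValueError("empty blow series collection")
    rows = []
    for s in series:
        ok1, best1 = qc_blow(s.fev1)
        ok2, best2 = qc_blow(s.fvc)
        rows.append((s.individual_id, ok1 and ok2, best1, best2))
    return pd.DataFrame(rows, columns=["individual_id", "qc_pass", "best_fev1", "best_fvc"])


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("phenotype has zero variance; cannot standardize")
    return (x - x.mean()) / sd


def derive_phenotypes(qc_table: pd.DataFrame) -> SpirometryPhenotypes:
    """Z-scored volumes, the raw FEV1/FVC ratio, and the COPD flag.

    Standardization is over QC-passing individuals only; failing rows get
    NaN phenotypes but keep their identifiers.
    """
    passing = qc_table["qc_pass"].to_numpy(bool)
    if passing.sum() == 0:
        raise ValueError("no QC-passing individuals")
    best_fev1 = qc_table["best_fev1"].to_numpy(float)
    best_fvc = qc_table["best_fvc"].to_numpy(float)
    if np.any(best_fvc[passing] <= 0):
        raise ValueError("FVC must be positive")

    n = len(qc_table)
    fev1_z = np.full(n, np.nan)
    fvc_z = np.full(n, np.nan)
    ratio = np.full(n, np.nan)
    fev1_z[passing] = _zscore(best_fev1[passing])
    fvc_z[passing] = _zscore(best_fvc[passing])
    ratio[passing] = best_fev1[passing] / best_fvc[passing]
    copd = ratio < COPD_RATIO_THRESHOLD

    return SpirometryPhenotypes(
        individual_id=qc_table["individual_id"].to_numpy(),
        best_fev1=best_fev1,
        best_fvc=best_fvc,
        fev1_z=fev1_z,
        fvc_z=fvc_z,
        ratio=ratio,
        copd=copd,
        qc_pass=passing,
    )


# ---------------------------------------------------------------------------
# variant QC
# ---------------------------------------------------------------------------

def hwe_exact_test(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy–Weinberg test p-value by enumerating heterozygote counts.

    Mid-less two-sided p: the sum of probabilities of all heterozygote
    counts (given the minor-allele count) no more likely than the
    observed one.
    """
    if min(n_het, n_hom_minor, n_hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    if n_minor > n:  # ensure "minor" really is minor
        n_minor = 2 * n - n_minor

    # heterozygote count shares the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    valid = hom_major >= 0
    hets, hom_minor, hom_major = hets[valid], hom_minor[valid], hom_major[valid]

    # log P(het = h | n, n_minor) up to a constant
    logp = (
        hets * np.log(2.0)
        - special.gammaln(hets + 1)
        - special.gammaln(hom_minor + 1)
        - special.gammaln(hom_major + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == n_het]
    if p_obs.size == 0:
        raise ValueError("inconsistent genotype counts")
    return float(min(1.0, p[p <= p_obs[0] * (1 + 1e-12)].sum()))


def hard_call(dosages: np.ndarray, tolerance: float = 0.1):
    """Round dosages to genotypes; values further than ``tolerance`` from an
    integer are treated as missing (NaN)."""
    calls = np.rint(dosages)
    missing = np.abs(dosages - calls) > tolerance
    calls = calls.astype(float)
    calls[missing] = np.nan
    return calls


def variant_qc(
    panel: GenotypePanel,
    hwe_p_threshold: float = 1e-5,
    call_rate_threshold: float = 0.95,
    maf_threshold: float = 0.005,
    control_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant QC: HWE exact test, call rate, MAF.

    ``control_mask`` restricts the HWE test to cancer-free individuals
    when an outcome label exists.  Imputation INFO filtering does not
    apply to simulated hard genotypes and is recorded as skipped.

    Returns a frame with per-variant metrics, per-filter flags and the
    combined ``retained`` flag.
    """
    calls = hard_call(panel.dosages)
    n = calls.shape[0]
    called = ~np.isnan(calls)
    call_rate = called.mean(axis=0)

    hwe_calls = calls if control_mask is None else calls[np.asarray(control_mask, bool)]
    hwe_p = np.empty(panel.n_variants)
    maf = np.empty(panel.n_variants)
    for j in range(panel.n_variants):
        col = hwe_calls[:, j]
        col = col[~np.isnan(col)]
        n_hom_major = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_hom_minor = int((col == 2).sum())
        hwe_p[j] = hwe_exact_test(n_het, n_hom_minor, n_hom_major)
        allj = calls[:, j]
        allj = allj[~np.isnan(allj)]
        freq = allj.mean() / 2 if allj.size else 0.0
        maf[j] = min(freq, 1 - freq)

    fail_hwe = hwe_p < hwe_p_threshold
    fail_call = call_rate < call_rate_threshold
    fail_maf = maf < maf_threshold
    return pd.DataFrame(
        {
            "SNP": panel.variant_ids,
            "hwe_p": hwe_p,
            "call_rate": call_rate,
            "maf": maf,
            "fail_hwe": fail_hwe,
            "fail_call_rate": fail_call,
            "fail_maf": fail_maf,
            "retained": ~(fail_hwe | fail_call | fail_maf),
            "info_filter": "skipped",
        }
    )


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------

def run_gwas(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    sample_size: int | None = None,
) -> pd.DataFrame:
    """Per-variant OLS of phenotype on dosage plus covariates.

    Uses the Frisch–Waugh–Lovell projection: phenotype and dosages are
    residualized against the covariates (plus intercept) once, then each
    variant is a simple regression on its residualized dosage, which is
    algebraically identical to the full multiple regression coefficient.
    Two-sided p-values come from the t distribution with
    n - (covariates+1) - 1 degrees of freedom.

    Returns a summary-stats table plus a ``lambda_gc`` attribute in
    ``DataFrame.attrs`` (median chi-square over 0.4549).
    """
    y = np.asarray(phenotype, dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing phenotype among analyzed rows")
    n = y.size
    if n != panel.n_individuals:
        raise ValueError("phenotype length does not match panel")

    if covariates is None:
        C = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        C = np.column_stack([np.ones(n), covariates])
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        raise ValueError("covariate matrix is rank deficient")

    # residualize via QR
    Q, _ = np.linalg.qr(C)
    y_res = y - Q @ (Q.T @ y)
    G_res = panel.dosages - Q @ (Q.T @ panel.dosages)

    df = n - C.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")

    gss = (G_res**2).sum(axis=0)
    gss = np.where(gss == 0, np.nan, gss)
    beta = (G_res * y_res[:, None]).sum(axis=0) / gss
    resid_ss = np.maximum((y_res**2).sum() - beta**2 * gss, 0.0)
    sigma2 = resid_ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / gss)
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    se = np.where(se > 0, se, 1e-300)
    p = 2 * stats.t.sf(np.abs(tstat), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    eaf = panel.allele_freq()
    out = pd.DataFrame(
        {
            "SNP": panel.variant_ids,
            "CHR": panel.chrom,
            "POS": panel.pos,
            "A1": panel.effect_allele,
            "A2": panel.other_allele,
            "EAF": np.clip(eaf, 1e-6, 1 - 1e-6),
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": sample_size if sample_size is not None else n,
        }
    )
    chi2 = tstat**2
    out.attrs["lambda_gc"] = float(np.nanmedian(chi2) / CHI2_1_MEDIAN)
    return out


# ---------------------------------------------------------------------------
# clumping and selection
# ---------------------------------------------------------------------------

def clump(
    stats_table: pd.DataFrame,
    panel: GenotypePanel,
    r2_threshold: float = 0.05,
    window_kb: float = 10_000.0,
) -> list[str]:
    """Greedy LD clumping: best remaining p becomes an index variant and
    removes everything within the window with r^2 >= threshold.

    Ties on p are broken by position, then variant id, so the output is
    invariant to input row order.
    """
    idx_map = {v: i for i, v in enumerate(panel.variant_ids)}
    missing = [s for s in stats_table["SNP"] if s not in idx_map]
    if missing:
        raise KeyError(f"variants absent from panel: {missing[:5]}")

    work = stats_table[["SNP", "CHR", "POS", "P"]].copy()
    work = work.sort_values(["P", "POS", "SNP"], kind="mergesort").reset_index(drop=True)
    window_bp = window_kb * 1000.0

    alive = np.ones(len(work), dtype=bool)
    chrom = work["CHR"].to_numpy()
    pos = work["POS"].to_numpy(float)
    cols = [idx_map[s] for s in work["SNP"]]
    index_variants: list[str] = []

    for i in range(len(work)):
        if not alive[i]:
            continue
        index_variants.append(work.at[i, "SNP"])
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        near[i] = False
        for j in np.flatnonzero(near):
            if panel.ld_r2(cols[i], cols[j]) >= r2_threshold:
                alive[j] = False
        alive[i] = False
    return index_variants


def select_instruments(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    panel: GenotypePanel,
    discovery_p: float = 5e-8,
    replication_p: float = 0.05,
    clump_r2: float = 0.05,
    clump_window_kb: float = 10_000.0,
    weight_stage: str = "discovery",
    trait: str = "exposure",
    scale: str = "per-SD",
) -> InstrumentSet:
    """Two-stage selection: clump the discovery scan, then require
    discovery P below threshold and nominal, sign-consistent replication.

    Instrument weights default to the discovery betas (replication used
    only for filtering, avoiding double use of the selected sample);
    ``weight_stage='replication'`` switches.  Strength metrics use the
    replication (independent) z-scores.
    """
    if weight_stage not in ("discovery", "replication"):
        raise ValueError("weight_stage must be 'discovery' or 'replication'")

    disc = discovery[discovery["P"] < discovery_p]
    if len(disc) == 0:
        empty = pd.DataFrame(
            columns=["SNP", "CHR", "POS", "A1", "A2", "BETA", "SE", "P",
                     "beta_repl", "se_repl", "p_repl", "r2"]
        )
        return InstrumentSet(empty, trait, scale, 0.0, 0.0,
                             discovery_p, replication_p, clump_r2, clump_window_kb)

    index_ids = clump(disc, panel, clump_r2, clump_window_kb)
    disc = disc.set_index("SNP").loc[index_ids].reset_index()

    repl = replication.set_index("SNP")
    missing = [s for s in disc["SNP"] if s not in repl.index]
    if missing:
        raise KeyError(f"variants missing from replication table: {missing[:5]}")
    r = repl.loc[disc["SNP"]]

    keep = (r["P"].to_numpy() < replication_p) & (
        np.sign(r["BETA"].to_numpy()) == np.sign(disc["BETA"].to_numpy())
    )
    selected = disc[keep].copy()
    r = r[keep]
    selected["beta_repl"] = r["BETA"].to_numpy()
    selected["se_repl"] = r["SE"].to_numpy()
    selected["p_repl"] = r["P"].to_numpy()
    n_repl = float(np.median(r["N"])) if len(r) else 0.0

    if len(selected):
        z_repl = (selected["beta_repl"] / selected["se_repl"]).to_numpy()
        selected["r2"] = z_repl**2 / (z_repl**2 + n_repl - 2)
        total_r2, f_stat = instrument_strength(z_repl, int(n_repl))
    else:
        selected["r2"] = []
        total_r2, f_stat = 0.0, 0.0

    if weight_stage == "replication":
        selected["BETA"] = selected["beta_repl"]
        selected["SE"] = selected["se_repl"]

    return InstrumentSet(
        table=selected.reset_index(drop=True),
        trait=trait,
        scale=scale,
        r_squared=float(total_r2),
        f_statistic=float(f_stat),
        discovery_p_threshold=discovery_p,
        replication_p_threshold=replication_p,
        clump_r2=clump_r2,
        clump_window_kb=clump_window_kb,
    )


def instrument_strength(z: np.ndarray, n: int) -> tuple[float, float]:
    """Total variance explained and F-statistic from independent-sample z-scores.

    Per-variant ``r2_j = z_j^2 / (z_j^2 + n - 2)``; ``R2 = sum r2_j``;
    ``F = R2 (n - 1 - J) / ((1 - R2) J)``.
    """
    z = np.asarray(z, dtype=float)
    j = z.size
    if n <= j + 1:
        raise ValueError("sample size must exceed the instrument count + 1")
    r2j = z**2 / (z**2 + n - 2)
    r2 = float(r2j.sum())
    f = r2 * (n - 1 - j) / ((1 - r2) * j) if j else 0.0
    return r2, float(f)
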