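"""Core data containers shared across the pipeline.

The tab-delimited summary-statistics convention used throughout is the
ten-column layout ``SNP CHR POS A1 A2 EAF BETA SE P N``: one row per
variant, ``A1`` the effect allele, ``BETA`` the per-allele effect in trait
units (log-odds for binary outcomes), ``EAF`` the effect-allele frequency.
A :class:`pandas.DataFrame` with these columns is the pipeline's lingua
franca ("summary-stats table"); helpers in :mod:`pulmo_mr.io` read, write
and validate it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

SUMSTATS_COLUMNS = ["SNP", "CHR", "POS", "A1", "A2", "EAF", "BETA", "SE", "P", "N"]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: A/T and C/G pairs cannot be disambiguated from allele labels alone.
PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class GenotypePanel:
    """Simulated dosage panel with block-structured linkage disequilibrium.

    Dosages are additive allele counts in [0, 2] (individuals x variants).
    Variants within a block are correlated through a latent autoregressive
    Gaussian copula; variants in different blocks are independent and are
    placed more than one clumping window (10,000 kb) apart so LD-based
    operations never reach across blocks.
    """

    variant_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    dosages: np.ndarray
    block_id: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Empirical effect-allele frequency per variant."""
        return self.dosages.mean(axis=0) / 2.0

    def index_of(self, variant_id: str) -> int:
        idx = np.flatnonzero(self.variant_ids == variant_id)
        if idx.size == 0:
            raise KeyError(f"variant {variant_id!r} not in panel")
        return int(idx[0])

    def ld_r2(self, i: int, j: int) -> float:
        """Squared dosage correlation between variants i and j."""
        gi = self.dosages[:, i]
        gj = self.dosages[:, j]
        si, sj = gi.std(), gj.std()
        if si == 0 or sj == 0:
            return 0.0
        r = float(np.corrcoef(gi, gj)[0, 1])
        return r * r


@dataclass
class BlowSeries:
    """Ordered spirometry blows (FEV1 and FVC volumes, litres) for one person."""

    individual_id: str
    fev1: np.ndarray
    fvc: np.ndarray

    def __post_init__(self) -> None:
        self.fev1 = np.asarray(self.fev1, dtype=float)
        self.fvc = np.asarray(self.fvc, dtype=float)
        if self.fev1.size == 0:
            raise ValueError("a blow series needs at least one blow")
        if np.any(self.fev1 <= 0) or np.any(self.fvc <= 0):
            raise ValueError("blow volumes must be positive")


@dataclass
class SimulationScenario:
    """Generative settings for a two-sample MR cohort simulation.

    The binary outcome is generated on the log-odds scale, so ``theta`` is
    the true causal log odds ratio per unit of (unit-variance) exposure.
    ``fraction_invalid`` instruments receive direct (horizontally
    pleiotropic) outcome effects with mean ``alpha_mean``; when
    ``balanced`` the direct effects are zero-mean, the setting under which
    the InSIDE-type estimators remain consistent.
    """

    n_exposure: int = 20_000
    n_outcome: int = 20_000
    m_variants: int = 200
    n_causal: int = 100
    theta: float = 0.0
    h2_exposure: float = 0.15
    fraction_invalid: float = 0.0
    alpha_mean: float = 0.0
    alpha_sd: float = 0.05
    balanced: bool = True
    confounder_on_exposure: float = 0.3
    confounder_on_outcome: float = 0.3
    case_fraction: float = 0.34
    seed: int = 0

    def validate(self) -> None:
        for name in ("h2_exposure", "fraction_invalid"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0, 1)")
        if self.n_causal > self.m_variants:
            raise ValueError("n_causal cannot exceed m_variants")
        if self.n_causal < 1:
            raise ValueError("at least one causal variant required")


@dataclass
class HarmonizedSet:
    """Aligned exposure/outcome effect pairs, ready for MR estimation.

    ``table`` has one row per retained variant with columns ``SNP``,
    ``A1``, ``A2``, ``beta_exp``, ``se_exp``, ``beta_out``, ``se_out``,
    ``eaf_exp``, ``eaf_out`` and optionally ``proxy_of`` / ``proxy_r2``.
    ``exclusions`` records dropped variants with a machine-readable
    reason.  ``truth`` carries simulation ground truth (true causal
    effect, per-variant validity) purely for evaluation; no estimator
    reads it.
    """

    table: pd.DataFrame
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    scale: str = "per-SD"
    impairment_oriented: bool = False
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["SNP", "reason"])
    )
    truth: Optional[dict] = None

    @property
    def n_instruments(self) -> int:
        return len(self.table)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        t = self.table
        return (
            t["beta_exp"].to_numpy(float),
            t["se_exp"].to_numpy(float),
            t["beta_out"].to_numpy(float),
            t["se_out"].to_numpy(float),
        )

    def exclusion_counts(self) -> pd.Series:
        return self.exclusions["reason"].value_counts()

    @classmethod
    def from_arrays(
        cls,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        snp=None,
        **kwargs,
    ) -> "HarmonizedSet":
        beta_exp = np.asarray(beta_exp, dtype=float)
        if snp is None:
            snp = [f"rs{i}" for i in range(beta_exp.size)]
        table = pd.DataFrame(
            {
                "SNP": snp,
                "A1": "A",
                "A2": "G",
                "beta_exp": beta_exp,
                "se_exp": np.asarray(se_exp, dtype=float),
                "beta_out": np.asarray(beta_out, dtype=float),
                "se_out": np.asarray(se_out, dtype=float),
                "eaf_exp": 0.5,
                "eaf_out": 0.5,
            }
        )
        return cls(table=table, **kwargs)


@dataclass
class MRResult:
    """One estimator's causal estimate on the log-odds scale."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_instruments: int
    heterogeneity_scale: float = 1.0
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_p: Optional[float] = None
    overdispersion: Optional[float] = None
    n_bootstrap: Optional[int] = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.theta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["OR"] = self.odds_ratio
        d["OR_ci_low"], d["OR_ci_high"] = self.or_ci
        return d


@dataclass
class SpirometryPhenotypes:
    """Derived lung-function phenotypes after blow QC."""

    individual_id: np.ndarray
    best_fev1: np.ndarray
    best_fvc: np.ndarray
    fev1_z: np.ndarray
    fvc_z: np.ndarray
    ratio: np.ndarray
    copd: np.ndarray
    qc_pass: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_id,
                "best_fev1": self.best_fev1,
                "best_fvc": self.best_fvc,
                "fev1_z": self.fev1_z,
                "fvc_z": self.fvc_z,
                "ratio": self.ratio,
                "copd": self.copd,
                "qc_pass": self.qc_pass,
            }
        )


@dataclass
class InstrumentSet:
    """Variants passing two-stage selection, with strength metrics.

    ``table`` columns: SNP, CHR, POS, A1, A2, beta_disc, se_disc, p_disc,
    beta_repl, se_repl, p_repl, r2 (per-variant variance explained).
    """

    table: pd.DataFrame
    trait: str
    scale: str
    r_squared: float
    f_statistic: float
    discovery_p_threshold: float = 5e-8
    replication_p_threshold: float = 0.05
    clump_r2: float = 0.05
    clump_window_kb: float = 10_000.0

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table["SNP"])

    @property
    def n_instruments(self) -> int:
        return len(self.table)


@dataclass
class HeterogeneityReport:
    """Cochran's Q with modified second-order weights."""

    q: float
    df: int
    p: float
    q_contributions: np.ndarray
    outlier_flags: np.ndarray
    theta_min: float
    phi: float
    snp: np.ndarray


@dataclass
class SteigerReport:
    r2_exposure: np.ndarray
    r2_outcome: np.ndarray
    direction_exposure_to_outcome: bool
    z: float
    p: float
    indeterminate: bool
    failing_variants: np.ndarray


@dataclass
class NomeReport:
    """Instrument-precision diagnostic for MR-Egger regression dilution."""

    i2_gx: float
    q_gx: float
    df: int


@dataclass
class PowerSpec:
    """Inputs for the binary-outcome MR power approximation."""

    n_total: int
    case_fraction: float
    r_squared: float
    odds_ratio: float
    alpha: float = 0.05

    def validate(self) -> None:
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case fraction must be in (0, 1)")
        if not 0.0 < self.r_squared < 1.0:
            raise ValueError("R^2 must be in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class LDScoreTable:
    snp: np.ndarray
    l2: np.ndarray
    window_kb: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"SNP": self.snp, "L2": self.l2})


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    intercept: float
    intercept_se: float
    m_variants: int
    n_samples: float
    mean_chi2: float
    n_blocks: int


@dataclass
class GeneticCorrelation:
    rho_g: float
    rg: float
    se: float
    p: float
    cross_intercept: float
    h2_1: float
    h2_2: float


@dataclass
class PartitionReport:
    """Stratified heritability over user-supplied annotations."""

    table: pd.DataFrame  # annotation, tau, prop_h2, prop_h2_se, prop_snps, enrichment, enrichment_se, p, significant
    h2_total: float
    bonferroni_alpha: float


@dataclass
class GeneEffect:
    gene: str
    instruments: list[str]
    theta: float
    se: float
    p: float
    method: str
    consistency: str = "unclassified"

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.theta))
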