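"""End-to-end orchestration from a single declarative config.

``run_pipeline`` simulates the study conditions, develops instruments
in the exposure cohort (70/30 discovery/replication split), estimates
outcome effects at the instruments by per-variant logistic regression
in the disjoint outcome cohort, harmonizes, runs the five estimators
with the full diagnostic battery, and (optionally) an LD-score
heritability/genetic-correlation analysis.  Every stage writes a TSV or
JSON artefact and logs its in/out counts; runs are deterministic given
the master seed (per-stage seeds derive from it by fixed offsets).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from . import diagnostics, estimators, gwas, harmonize, ldsc, synthetic
from .containers import PowerSpec, SimulationScenario

logger = logging.getLogger("pulmo_mr")

# fixed per-stage seed offsets from the master seed
_SEED_OFFSETS = {
    "panel_exposure": 1,
    "panel_outcome": 2,
    "cohorts": 3,
    "split": 4,
    "bootstrap": 5,
    "polygenic": 6,
}


@dataclass
class PipelineConfig:
    """Declarative pipeline settings; thresholds default to the study's values."""

    # simulation scenario
    n_exposure: int = 8000
    n_outcome: int = 8000
    m_variants: int = 300
    block_size: int = 5
    n_causal: int = 60
    theta: float = 0.3
    h2_exposure: float = 0.15
    fraction_invalid: float = 0.0
    alpha_mean: float = 0.0
    alpha_sd: float = 0.05
    balanced: bool = True
    case_fraction: float = 0.34
    maf_low: float = 0.1
    maf_high: float = 0.5
    ld_rho: float = 0.6
    # instrument selection
    discovery_fraction: float = 0.70
    discovery_p: float = 5e-8
    replication_p: float = 0.05
    clump_r2: float = 0.05
    clump_window_kb: float = 10_000.0
    # harmonization
    palindrome_maf: float = 0.42
    proxy_r2: float = 0.90
    # diagnostics
    q_alpha: float | None = None  # None -> Bonferroni 0.05/J
    outlier_filtering: bool = True
    screen_thresholds: tuple[float, float] = (5e-8, 1e-5)
    power_or: float = 1.25
    # estimators
    methods: tuple[str, ...] = ("ivw", "ml", "wm", "egger", "raps")
    wm_bootstrap: int = 500
    # LDSC stage
    run_ldsc: bool = True
    ldsc_m: int = 2000
    ldsc_n: int = 20_000
    ldsc_h2: float = 0.15
    ldsc_rg: float = 0.3
    ldsc_blocks: int = 20
    # bookkeeping
    seed: int = 1
    output_dir: str = "pulmo_mr_run"

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["screen_thresholds"] = list(self.screen_thresholds)
        d["methods"] = list(self.methods)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "screen_thresholds" in d:
            d["screen_thresholds"] = tuple(d["screen_thresholds"])
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        return cls(**d)


def _logistic_scan(dosages: np.ndarray, outcome: np.ndarray, cols, panel, n_label):
    """Per-variant logistic regression of case status on dosage."""
    rows = []
    for j in cols:
        X = sm.add_constant(dosages[:, j])
        try:
            fit = sm.Logit(outcome, X).fit(disp=0, maxiter=100)
            beta, se = float(fit.params[1]), float(fit.bse[1])
            p = float(fit.pvalues[1])
        except Exception:  # separation etc.
            beta, se, p = 0.0, np.inf, 1.0
        freq = dosages[:, j].mean() / 2
        rows.append(
            {
                "SNP": panel.variant_ids[j],
                "CHR": panel.chrom[j],
                "POS": panel.pos[j],
                "A1": panel.effect_allele[j],
                "A2": panel.other_allele[j],
                "EAF": float(np.clip(freq, 1e-6, 1 - 1e-6)),
                "BETA": beta,
                "SE": se,
                "P": max(p, np.finfo(float).tiny),
                "N": n_label,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> dict:
    """Run all stages; returns the summary report (also written to disk)."""
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    seed = config.seed
    report: dict = {"seed": seed, "counts": {}}

    # --- stage 0: simulate -------------------------------------------------
    # one panel, split into disjoint exposure/outcome samples sharing the
    # variant map (ids, positions, alleles) as a two-sample design requires
    panel_all = synthetic.simulate_genotype_panel(
        config.n_exposure + config.n_outcome, config.m_variants, config.block_size,
        (config.maf_low, config.maf_high), config.ld_rho,
        seed=seed + _SEED_OFFSETS["panel_exposure"],
    )
    panel_x, panel_y = synthetic.split_panel(panel_all, config.n_exposure)
    scenario = SimulationScenario(
        n_exposure=config.n_exposure, n_outcome=config.n_outcome,
        m_variants=config.m_variants, n_causal=config.n_causal,
        theta=config.theta, h2_exposure=config.h2_exposure,
        fraction_invalid=config.fraction_invalid, alpha_mean=config.alpha_mean,
        alpha_sd=config.alpha_sd, balanced=config.balanced,
        case_fraction=config.case_fraction,
        seed=seed + _SEED_OFFSETS["cohorts"],
    )
    cohorts = synthetic.simulate_mr_cohorts(panel_x, panel_y, scenario)
    logger.info("simulated cohorts: n_exposure=%d n_outcome=%d case fraction=%.3f",
                config.n_exposure, config.n_outcome, cohorts["outcome"].mean())
    report["counts"]["case_fraction"] = float(cohorts["outcome"].mean())

    # --- stage 1: exposure GWAS with 70/30 split ---------------------------
    rng_split = np.random.default_rng(seed + _SEED_OFFSETS["split"])
    n = config.n_exposure
    disc_mask = rng_split.uniform(size=n) < config.discovery_fraction
    exposure = cohorts["exposure"]

    panel_disc = dataclasses.replace(panel_x, dosages=panel_x.dosages[disc_mask])
    panel_repl = dataclasses.replace(panel_x, dosages=panel_x.dosages[~disc_mask])
    disc_stats = gwas.run_gwas(panel_disc, exposure[disc_mask])
    repl_stats = gwas.run_gwas(panel_repl, exposure[~disc_mask])
    disc_stats.to_csv(out / "gwas_discovery.tsv", sep="\t", index=False)
    report["lambda_gc_discovery"] = disc_stats.attrs["lambda_gc"]

    instruments = gwas.select_instruments(
        disc_stats, repl_stats, panel_disc,
        discovery_p=config.discovery_p, replication_p=config.replication_p,
        clump_r2=config.clump_r2, clump_window_kb=config.clump_window_kb,
    )
    logger.info("selected %d instruments (R2=%.4f, F=%.1f)",
                instruments.n_instruments, instruments.r_squared,
                instruments.f_statistic)
    report["counts"]["instruments_selected"] = instruments.n_instruments
    report["instrument_r2"] = instruments.r_squared
    report["instrument_f"] = instruments.f_statistic
    if instruments.n_instruments < 3:
        raise RuntimeError(
            "fewer than three instruments selected; increase sample size or h2"
        )
    instruments.table.to_csv(out / "instruments.tsv", sep="\t", index=False)

    # --- stage 2: outcome scan at instruments + harmonization --------------
    cols = [panel_y.index_of(s) for s in instruments.variant_ids]
    outcome_stats = _logistic_scan(
        panel_y.dosages, cohorts["outcome"], cols, panel_y, config.n_outcome
    )
    outcome_stats.to_csv(out / "outcome_stats.tsv", sep="\t", index=False)

    exp_stats = instruments.table.rename(columns={"BETA": "BETA", "SE": "SE", "P": "P"})
    exp_stats = exp_stats.assign(EAF=[
        float(np.clip(panel_x.allele_freq()[panel_x.index_of(s)], 1e-6, 1 - 1e-6))
        for s in exp_stats["SNP"]
    ], N=config.n_exposure)
    hset = harmonize.harmonize_pair(
        exp_stats, outcome_stats, instruments,
        palindrome_maf=config.palindrome_maf,
    )
    report["counts"]["harmonized"] = hset.n_instruments
    report["counts"]["excluded_by_reason"] = {
        str(k): int(v) for k, v in hset.exclusion_counts().items()
    }
    hset.table.to_csv(out / "harmonized.tsv", sep="\t", index=False)
    hset.exclusions.to_csv(out / "harmonization_exclusions.tsv", sep="\t", index=False)

    # --- stage 3: diagnostics + outlier filtering --------------------------
    het = diagnostics.cochran_q_modified(hset)
    if config.outlier_filtering:
        filtered, removal_log = diagnostics.filter_outliers(hset, q_alpha=config.q_alpha)
    else:
        filtered, removal_log = hset, pd.DataFrame(columns=["SNP", "q_contribution", "round"])
    removal_log.to_csv(out / "outlier_removals.tsv", sep="\t", index=False)
    report["counts"]["outliers_removed"] = int(len(removal_log))
    report["counts"]["instruments_final"] = filtered.n_instruments

    nome = diagnostics.i2_gx(filtered)
    steiger_rep = diagnostics.steiger(filtered, config.n_exposure, config.n_outcome)
    power = diagnostics.power_binary(PowerSpec(
        n_total=config.n_outcome, case_fraction=config.case_fraction,
        r_squared=max(instruments.r_squared, 1e-6), odds_ratio=config.power_or,
    ))
    report["diagnostics"] = {
        "q": het.q, "q_df": het.df, "q_p": het.p, "phi": het.phi,
        "i2_gx": nome.i2_gx,
        "steiger_direction_ok": steiger_rep.direction_exposure_to_outcome,
        "steiger_p": steiger_rep.p,
        "power_at_or": {"odds_ratio": config.power_or, "power": power},
    }

    # --- stage 4: estimators -----------------------------------------------
    method_fns = {
        "ivw": lambda s: estimators.ivw(s, random_effects=True),
        "ml": estimators.maximum_likelihood,
        "wm": lambda s: estimators.weighted_median(
            s, n_bootstrap=config.wm_bootstrap,
            seed=seed + _SEED_OFFSETS["bootstrap"]),
        "egger": estimators.mr_egger,
        "raps": estimators.mr_raps,
    }
    rows = []
    for name in config.methods:
        if name not in method_fns:
            raise ValueError(f"unknown estimator {name!r}")
        res = method_fns[name](filtered)
        rows.append(res.to_dict())
    est_table = pd.DataFrame(rows)
    est_table.to_csv(out / "estimates.tsv", sep="\t", index=False)
    report["estimates"] = rows
    report["true_theta"] = config.theta

    # --- stage 5: LDSC (optional) ------------------------------------------
    if config.run_ldsc:
        pg = synthetic.simulate_polygenic_pair(
            config.ldsc_n, config.ldsc_n, config.ldsc_m,
            config.ldsc_h2, config.ldsc_h2, config.ldsc_rg,
            seed=seed + _SEED_OFFSETS["polygenic"],
        )
        h2 = ldsc.estimate_h2(pg["z1"], config.ldsc_n, pg["ld_scores"],
                              n_blocks=config.ldsc_blocks)
        rg = ldsc.estimate_rg(pg["z1"], pg["z2"], config.ldsc_n, config.ldsc_n,
                              pg["ld_scores"], n_blocks=config.ldsc_blocks)
        report["ldsc"] = {
            "h2": h2.h2, "h2_se": h2.se, "intercept": h2.intercept,
            "rg": rg.rg, "rg_se": rg.se,
            "true_h2": config.ldsc_h2, "true_rg": config.ldsc_rg,
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
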