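"""Stage 6: gene-level effects of lung tissue expression on cancer risk.

Lung-function instruments that are also cis-eQTLs serve as instruments
for gene expression.  Genes with a single eQTL get a Wald ratio; genes
with multiple eQTLs are LD-pruned to independent variants (r^2 < 0.05)
and combined by fixed-effect IVW (a random-effects flag is provided).
Significance uses a Bonferroni threshold computed from the number of
genes actually tested.

The direction-consistency classification asks whether the allele that
increases expression both impairs lung function and raises cancer risk
(or the converse); effects with mismatched signs point at pleiotropic
paths not operating through pulmonary impairment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneEffect, GenotypePanel, HarmonizedSet
from .estimators import ivw, wald_ratio


def _prune_ld(variant_ids: list[str], panel: GenotypePanel, r2_threshold: float = 0.05):
    """Greedy prune to a mutually independent subset (first-come order)."""
    kept: list[str] = []
    for vid in variant_ids:
        i = panel.index_of(vid)
        if all(panel.ld_r2(i, panel.index_of(k)) < r2_threshold for k in kept):
            kept.append(vid)
    return kept


def gene_effect(
    gene: str,
    eqtl_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    panel: GenotypePanel | None = None,
    prune_r2: float = 0.05,
    random_effects: bool = False,
) -> GeneEffect:
    """Causal effect of one gene's expression on the outcome.

    ``eqtl_stats`` holds the per-variant expression effects (columns
    SNP, BETA, SE) for this gene; ``outcome_stats`` the harmonized
    outcome effects at the same variants.  Multi-eQTL genes are pruned
    at ``prune_r2`` (needs ``panel``) before IVW.
    """
    merged = eqtl_stats.merge(outcome_stats, on="SNP", suffixes=("_exp", "_out"))
    if len(merged) == 0:
        raise ValueError(f"no harmonized eQTL for gene {gene}")

    ids = list(merged["SNP"])
    if len(ids) > 1 and panel is not None:
        ids = _prune_ld(ids, panel, prune_r2)
        merged = merged[merged["SNP"].isin(ids)]

    if len(merged) == 1:
        row = merged.iloc[0]
        res = wald_ratio(row["BETA_exp"], row["SE_exp"], row["BETA_out"], row["SE_out"])
        method = "wald"
    else:
        hset = HarmonizedSet.from_arrays(
            merged["BETA_exp"], merged["SE_exp"], merged["BETA_out"], merged["SE_out"],
            snp=list(merged["SNP"]),
        )
        res = ivw(hset, random_effects=random_effects)
        method = "ivw_re" if random_effects else "ivw_fe"

    return GeneEffect(
        gene=gene,
        instruments=list(merged["SNP"]),
        theta=res.theta,
        se=res.se,
        p=res.p,
        method=method,
    )


def bonferroni_threshold(n_genes_tested: int, alpha: float = 0.05) -> float:
    """Per-gene significance threshold from the genes actually tested."""
    if n_genes_tested < 1:
        raise ValueError("need at least one tested gene")
    return alpha / n_genes_tested


def classify_consistency(
    expr_to_function_beta: float,
    expr_to_function_p: float,
    expr_to_cancer_beta: float,
    expr_to_cancer_p: float,
    p_threshold: float = 0.05,
) -> str:
    """Label a gene's direction pattern.

    ``consistent``: increased expression goes with impaired function and
    increased cancer risk, or with better function and decreased risk.
    ``inconsistent``: the signs disagree with that pattern.
    ``indeterminate``: either association fails the declared threshold.
    The labels are invariant to jointly flipping the coded allele (both
    betas negate together, leaving the sign product unchanged).
    """
    if expr_to_function_p > p_threshold or expr_to_cancer_p > p_threshold:
        return "indeterminate"
    # impaired function = negative function effect; pattern holds when the
    # function and cancer effects have opposite signs
    if np.sign(expr_to_function_beta) * np.sign(expr_to_cancer_beta) < 0:
        return "consistent"
    return "inconsistent"


def gene_effect_table(
    gene_effects: list[GeneEffect], alpha: float = 0.05
) -> pd.DataFrame:
    """Tidy per-gene table with the Bonferroni significance flag."""
    threshold = bonferroni_threshold(len(gene_effects), alpha)
    z = stats.norm.ppf(0.975)
    rows = []
    for ge in gene_effects:
        rows.append(
            {
                "gene": ge.gene,
                "n_instruments": len(ge.instruments),
                "method": ge.method,
                "OR": ge.odds_ratio,
                "OR_ci_low": float(np.exp(ge.theta - z * ge.se)),
                "OR_ci_high": float(np.exp(ge.theta + z * ge.se)),
                "p": ge.p,
                "significant": ge.p < threshold,
                "consistency": ge.consistency,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = threshold
    return out


def simulate_eqtl_fixture(
    n_genes: int = 5,
    max_eqtls: int = 3,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Small synthetic eQTL fixture for documentation and tests.

    Returns (per-gene expression stats, outcome stats) with a known
    per-gene causal effect stored in each frame's ``attrs['theta']``.
    """
    rng = np.random.default_rng(seed)
    genes: dict[str, pd.DataFrame] = {}
    outcome_rows = []
    counter = 0
    for gi in range(n_genes):
        k = int(rng.integers(1, max_eqtls + 1))
        theta = float(rng.normal(0, 0.3))
        snps = [f"rs_eqtl_{counter + i}" for i in range(k)]
        counter += k
        beta_e = rng.uniform(0.2, 0.6, k) * rng.choice([-1, 1], k)
        se_e = np.full(k, 0.03)
        beta_o = theta * beta_e + rng.normal(0, 0.02, k)
        se_o = np.full(k, 0.02)
        g = pd.DataFrame({"SNP": snps, "BETA": beta_e, "SE": se_e})
        g.attrs["theta"] = theta
        genes[f"GENE{gi}"] = g
        outcome_rows += [
            {"SNP": s, "BETA": bo, "SE": so}
            for s, bo, so in zip(snps, beta_o, se_o)
        ]
    return genes, pd.DataFrame(outcome_rows)
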