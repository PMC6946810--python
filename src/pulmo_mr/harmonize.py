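"""Stage 2: allele harmonization, proxies, and unit scaling.

Exposure and outcome summary statistics are aligned to a common effect
allele.  Swapped allele labels flip the outcome effect sign; strand
flips are resolved by complementing alleles; palindromic (A/T, C/G)
variants are kept only when the allele frequency makes the strand
inferable (MAF <= 0.42 in both studies, with concordant frequencies
after orientation).  Multi-allelic entries are excluded.  Missing
outcome variants can be replaced by LD proxies (r^2 > 0.90) from a
reference panel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    COMPLEMENT,
    PALINDROMIC_PAIRS,
    GenotypePanel,
    HarmonizedSet,
    InstrumentSet,
)

PALINDROME_MAF_THRESHOLD = 0.42
PROXY_R2_THRESHOLD = 0.90


def _is_palindromic(a1: str, a2: str) -> bool:
    return (a1, a2) in PALINDROMIC_PAIRS


def _orient(a1_ref, a2_ref, a1, a2):
    """How do (a1, a2) relate to the reference pair?

    Returns one of 'same', 'swap', 'flip', 'flip_swap', or None when the
    allele sets are irreconcilable.
    """
    if (a1, a2) == (a1_ref, a2_ref):
        return "same"
    if (a1, a2) == (a2_ref, a1_ref):
        return "swap"
    c1, c2 = COMPLEMENT.get(a1), COMPLEMENT.get(a2)
    if (c1, c2) == (a1_ref, a2_ref):
        return "flip"
    if (c1, c2) == (a2_ref, a1_ref):
        return "flip_swap"
    return None


def harmonize_pair(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    instruments: InstrumentSet | list[str] | None = None,
    palindrome_maf: float = PALINDROME_MAF_THRESHOLD,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    scale: str = "per-SD",
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele.

    ``instruments`` restricts harmonization to a selected set (an
    :class:`InstrumentSet` or list of ids); by default every shared
    variant is harmonized.  Excluded variants are recorded with a
    machine-readable reason: ``missing_outcome``, ``multi_allelic``,
    ``allele_mismatch``, ``palindromic_intermediate_maf`` or
    ``palindromic_discordant_freq``.
    """
    if instruments is None:
        wanted = list(exposure["SNP"])
    elif isinstance(instruments, InstrumentSet):
        wanted = instruments.variant_ids
    else:
        wanted = list(instruments)

    exp = exposure.set_index("SNP")
    out = outcome.set_index("SNP")

    rows = []
    exclusions = []
    for snp in wanted:
        if snp not in exp.index:
            exclusions.append((snp, "missing_exposure"))
            continue
        if snp not in out.index:
            exclusions.append((snp, "missing_outcome"))
            continue
        e = exp.loc[snp]
        o = out.loc[snp]
        if isinstance(e, pd.DataFrame) or isinstance(o, pd.DataFrame):
            exclusions.append((snp, "multi_allelic"))
            continue
        ea1, ea2 = str(e["A1"]).upper(), str(e["A2"]).upper()
        oa1, oa2 = str(o["A1"]).upper(), str(o["A2"]).upper()
        if len({ea1, ea2}) != 2 or len({oa1, oa2}) != 2:
            exclusions.append((snp, "multi_allelic"))
            continue

        palindromic = _is_palindromic(ea1, ea2)
        orientation = _orient(ea1, ea2, oa1, oa2)
        if orientation is None:
            exclusions.append((snp, "allele_mismatch"))
            continue

        beta_out = float(o["BETA"])
        eaf_out = float(o["EAF"])
        if palindromic:
            # strand cannot be told from labels; use frequencies
            maf_e = min(e["EAF"], 1 - e["EAF"])
            maf_o = min(eaf_out, 1 - eaf_out)
            if maf_e > palindrome_maf or maf_o > palindrome_maf:
                exclusions.append((snp, "palindromic_intermediate_maf"))
                continue
            # orient by minor-allele side: the outcome's frequency for the
            # exposure's effect allele should fall on the same side of 0.5
            same_side = (e["EAF"] < 0.5) == (eaf_out < 0.5)
            if not same_side:
                eaf_out = 1 - eaf_out
                beta_out = -beta_out
            # concordance check after orientation
            if (e["EAF"] < 0.5) != (eaf_out < 0.5):
                exclusions.append((snp, "palindromic_discordant_freq"))
                continue
        else:
            if orientation in ("swap", "flip_swap"):
                beta_out = -beta_out
                eaf_out = 1 - eaf_out
            # 'flip' is a pure strand relabel: effect allele unchanged

        rows.append(
            {
                "SNP": snp,
                "A1": ea1,
                "A2": ea2,
                "beta_exp": float(e["BETA"]),
                "se_exp": float(e["SE"]),
                "beta_out": beta_out,
                "se_out": float(o["SE"]),
                "eaf_exp": float(e["EAF"]),
                "eaf_out": eaf_out,
            }
        )

    table = pd.DataFrame(
        rows,
        columns=["SNP", "A1", "A2", "beta_exp", "se_exp", "beta_out", "se_out",
                 "eaf_exp", "eaf_out"],
    )
    return HarmonizedSet(
        table=table,
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        scale=scale,
        exclusions=pd.DataFrame(exclusions, columns=["SNP", "reason"]),
    )


def find_proxy(
    missing_id: str,
    panel: GenotypePanel,
    available_ids,
    r2_threshold: float = PROXY_R2_THRESHOLD,
    window_kb: float = 10_000.0,
) -> tuple[str, float] | None:
    """Best LD proxy for a variant absent from the outcome table.

    Returns ``(proxy_id, r2)`` for the highest-r^2 candidate above the
    threshold among ``available_ids`` within the window, or None.  Ties
    break toward the smaller position.
    """
    i = panel.index_of(missing_id)
    available = set(available_ids) - {missing_id}
    window_bp = window_kb * 1000.0

    best: tuple[str, float] | None = None
    best_pos = None
    for j, vid in enumerate(panel.variant_ids):
        if vid not in available:
            continue
        if panel.chrom[j] != panel.chrom[i]:
            continue
        if abs(int(panel.pos[j]) - int(panel.pos[i])) > window_bp:
            continue
        r2 = panel.ld_r2(i, j)
        if r2 <= r2_threshold:
            continue
        if best is None or r2 > best[1] or (r2 == best[1] and panel.pos[j] < best_pos):
            best = (vid, r2)
            best_pos = panel.pos[j]
    return best


def substitute_proxies(
    instruments: InstrumentSet,
    outcome: pd.DataFrame,
    panel: GenotypePanel,
    r2_threshold: float = PROXY_R2_THRESHOLD,
) -> pd.DataFrame:
    """Replace instrument variants missing from the outcome table by proxies.

    The proxy keeps the index variant's exposure effect and contributes
    its own outcome effect (standard proxy semantics).  Returns the
    instrument table with ``SNP`` pointing at the outcome-side variant
    and ``proxy_of`` / ``proxy_r2`` recorded.
    """
    available = set(outcome["SNP"])
    table = instruments.table.copy()
    table["proxy_of"] = None
    table["proxy_r2"] = np.nan
    keep = np.ones(len(table), dtype=bool)
    for k, snp in enumerate(table["SNP"]):
        if snp in available:
            continue
        hit = find_proxy(snp, panel, available, r2_threshold)
        if hit is None:
            keep[k] = False
            continue
        proxy_id, r2 = hit
        j = panel.index_of(proxy_id)
        table.iloc[k, table.columns.get_loc("proxy_of")] = snp
        table.iloc[k, table.columns.get_loc("proxy_r2")] = r2
        table.iloc[k, table.columns.get_loc("SNP")] = proxy_id
        table.iloc[k, table.columns.get_loc("A1")] = panel.effect_allele[j]
        table.iloc[k, table.columns.get_loc("A2")] = panel.other_allele[j]
    return table[keep].reset_index(drop=True)


def rescale_units(hset: HarmonizedSet, mode: str) -> HarmonizedSet:
    """Apply the study's unit conventions to a harmonized set.

    ``per-SD``
        Identity for z-scored exposures (effects already per 1 SD).
    ``per-10%-ratio``
        For the FEV1/FVC ratio in natural 0–1 units: a 10% absolute
        decrease is 0.1 units, so exposure effects are multiplied by 10
        (the causal log-odds per 0.1 units is 0.1x the per-unit value).
    ``impairment-sign``
        Orient every exposure effect toward *decreasing* function
        (beta_exp >= 0 on the impairment scale) by jointly flipping
        (beta_exp, beta_out) where beta_exp > 0; applying it twice
        returns the original set.
    """
    table = hset.table.copy()
    scale = hset.scale
    impairment = hset.impairment_oriented
    if mode == "per-SD":
        pass
    elif mode == "per-10%-ratio":
        # beta_exp currently per 1.0 of ratio; express per 0.1 units so
        # that theta (outcome per exposure unit) shrinks by 10x
        table["beta_exp"] = table["beta_exp"] * 10.0
        table["se_exp"] = table["se_exp"] * 10.0
        scale = "per-10%-ratio"
    elif mode == "impairment-sign":
        if not impairment:
            # switch each function-increasing effect allele to the other
            # allele, then express the exposure as impairment (-function),
            # so every beta_exp ends >= 0 toward decreasing function
            flip = table["beta_exp"].to_numpy() > 0
            sign = np.where(flip, -1.0, 1.0)
            table["beta_exp"] = -(table["beta_exp"] * sign)
            table["beta_out"] = table["beta_out"] * sign
            eaf_exp = table["eaf_exp"].to_numpy(float)
            eaf_out = table["eaf_out"].to_numpy(float)
            table["eaf_exp"] = np.where(flip, 1 - eaf_exp, eaf_exp)
            table["eaf_out"] = np.where(flip, 1 - eaf_out, eaf_out)
            table["impairment_flip"] = flip
        else:
            # undo: applying the mode twice returns the original set
            flip = table["impairment_flip"].to_numpy(bool)
            sign = np.where(flip, -1.0, 1.0)
            table["beta_exp"] = -table["beta_exp"] * sign
            table["beta_out"] = table["beta_out"] * sign
            eaf_exp = table["eaf_exp"].to_numpy(float)
            eaf_out = table["eaf_out"].to_numpy(float)
            table["eaf_exp"] = np.where(flip, 1 - eaf_exp, eaf_exp)
            table["eaf_out"] = np.where(flip, 1 - eaf_out, eaf_out)
            table = table.drop(columns=["impairment_flip"])
        impairment = not impairment
    else:
        raise ValueError(f"unknown scale mode {mode!r}")

    return HarmonizedSet(
        table=table,
        exposure_name=hset.exposure_name,
        outcome_name=hset.outcome_name,
        scale=scale,
        impairment_oriented=impairment,
        exclusions=hset.exclusions,
        truth=hset.truth,
    )
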