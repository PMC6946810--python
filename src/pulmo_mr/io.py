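"""Readers/writers for the tab-delimited formats the pipeline exchanges.

Summary statistics use the ten-column ``SNP CHR POS A1 A2 EAF BETA SE P N``
layout; LD scores use ``SNP L2``; munged z-scores use ``SNP Z N``.
Instrument sets are a TSV with a JSON sidecar holding selection metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SUMSTATS_COLUMNS, InstrumentSet


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Check the summary-stats invariants; returns the frame unchanged."""
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-stats table missing columns: {missing}")
    if (df["SE"] <= 0).any():
        raise ValueError("standard errors must be positive")
    p = df["P"].to_numpy(float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    eaf = df["EAF"].to_numpy(float)
    if ((eaf <= 0) | (eaf >= 1)).any():
        raise ValueError("allele frequencies must lie in (0, 1)")
    return df


def read_sumstats(path) -> pd.DataFrame:
    return validate_sumstats(pd.read_csv(path, sep="\t"))


def write_sumstats(df: pd.DataFrame, path) -> None:
    validate_sumstats(df)
    df.to_csv(path, sep="\t", index=False, columns=SUMSTATS_COLUMNS)


def write_instruments(inst: InstrumentSet, path) -> None:
    """TSV of selected variants plus a ``.json`` sidecar with metadata."""
    path = Path(path)
    inst.table.to_csv(path, sep="\t", index=False)
    sidecar = {
        "trait": inst.trait,
        "scale": inst.scale,
        "r_squared": inst.r_squared,
        "f_statistic": inst.f_statistic,
        "discovery_p_threshold": inst.discovery_p_threshold,
        "replication_p_threshold": inst.replication_p_threshold,
        "clump_r2": inst.clump_r2,
        "clump_window_kb": inst.clump_window_kb,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_instruments(path) -> InstrumentSet:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return InstrumentSet(table=table, **meta)


def write_ld_scores(snp, l2, path) -> None:
    pd.DataFrame({"SNP": snp, "L2": np.asarray(l2, dtype=float)}).to_csv(
        path, sep="\t", index=False
    )


def read_ld_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if (df["L2"] < 1).any():
        raise ValueError("LD scores include the self r^2 and cannot be below 1")
    return df


def write_zscores(snp, z, n, path) -> None:
    pd.DataFrame({"SNP": snp, "Z": np.asarray(z, float), "N": n}).to_csv(
        path, sep="\t", index=False
    )


def read_zscores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
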