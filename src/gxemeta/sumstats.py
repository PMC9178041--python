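"""The on-disk summary-statistic dialect: a tab-separated table with one
row per SNP carrying the marginal, main and interaction coefficients, the
main/interaction covariance, both test p-values and the heterogeneity
statistics.  Missing values are written as "NA"."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SUMSTATS_COLUMNS", "load_sumstats", "write_sumstats"]

SUMSTATS_COLUMNS = [
    "SNPID", "CHR", "POS", "EA", "NEA", "EAF", "N",
    "BETA_MARG", "SE_MARG", "BETA_MAIN", "SE_MAIN",
    "BETA_INT", "SE_INT", "COV_MAIN_INT",
    "P_1DF", "P_2DF", "Q_HET", "P_HET",
]

_NUMERIC = [c for c in SUMSTATS_COLUMNS if c not in ("SNPID", "EA", "NEA")]


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write a summary table in the dialect (missing values as NA)."""
    cols = [c for c in SUMSTATS_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in SUMSTATS_COLUMNS
    ]
    df[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


def load_sumstats(path) -> pd.DataFrame:
    """Read and validate a summary-statistic TSV.

    A missing mandatory column is fatal (the error names it).  Rows
    violating the invariants (non-positive SEs alongside a beta, EAF
    outside (0,1), p-values outside (0,1]) are dropped with line-numbered
    log entries; the count is stored in ``attrs["n_invalid"]``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in SUMSTATS_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col}")
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    bad = pd.Series(False, index=df.index)
    for beta_col, se_col in (
        ("BETA_MARG", "SE_MARG"), ("BETA_MAIN", "SE_MAIN"), ("BETA_INT", "SE_INT"),
    ):
        bad |= df[beta_col].notna() & ~(df[se_col] > 0)
    bad |= ~((df["EAF"] > 0) & (df["EAF"] < 1))
    for p_col in ("P_1DF", "P_2DF"):
        bad |= df[p_col].notna() & ~((df[p_col] > 0) & (df[p_col] <= 1))
    bad |= df["P_HET"].notna() & ~((df["P_HET"] > 0) & (df["P_HET"] <= 1))

    for idx in df.index[bad]:
        logger.warning(
            "%s line %d: invalid record dropped (SNP %s)",
            path.name, idx + 2, df.loc[idx, "SNPID"],  # +2: header + 1-basing
        )
    out = df[~bad].reset_index(drop=True)
    out.attrs["n_invalid"] = int(bad.sum())
    return out
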