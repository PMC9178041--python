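"""Fixed-effects meta-analysis of per-cohort / per-stage summary statistics.

Two combination schemes are provided, mirroring how multi-cohort
interaction scans are pooled in practice:

* 1df inverse-variance weighting (IVW) of a single coefficient, with
  Cochran's Q heterogeneity statistic;
* joint 2df generalised least squares (GLS) of the (main, interaction)
  coefficient pair using each study's full 2x2 covariance, followed by the
  2df chi-square test.

``combine_stages`` merges a discovery-stage and a replication-stage table
of the summary-statistic dialect, harmonising effect alleles (strand
unambiguous flips negate the betas; palindromic A/T and C/G variants are
dropped), and ``mean_chi2_test`` is the set-level test that a group of
independent SNPs carries more interaction signal than chance (mean
chi-square above 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gwis import joint_2df_stat

logger = logging.getLogger(__name__)

__all__ = [
    "MetaRecord",
    "Meta2dfRecord",
    "ivw_meta",
    "joint_2df_meta",
    "combine_stages",
    "meta_sumstats",
    "mean_chi2_test",
]

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class MetaRecord:
    beta_meta: float
    se_meta: float
    p_meta: float
    Q: float
    p_het: Optional[float]  # None when k == 1
    k: int


@dataclass
class Meta2dfRecord:
    b_meta: np.ndarray
    V_meta: np.ndarray
    chi2_2df: float
    p_2df: float


def ivw_meta(estimates: Sequence[tuple]) -> MetaRecord:
    """Fixed-effects inverse-variance-weighted combination.

    estimates: iterable of (beta, se) pairs, all se > 0.
    """
    if len(estimates) == 0:
        raise ValueError("no estimates to combine")
    beta = np.array([b for b, _ in estimates], dtype=float)
    se = np.array([s for _, s in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / se**2
    # fsum keeps the combination exactly invariant to study order
    wsum = math.fsum(w)
    beta_meta = math.fsum(w * beta) / wsum
    se_meta = 1.0 / math.sqrt(wsum)
    z2 = (beta_meta / se_meta) ** 2
    Q = math.fsum(w * (beta - beta_meta) ** 2)
    k = len(beta)
    p_het = float(stats.chi2.sf(Q, df=k - 1)) if k > 1 else None
    return MetaRecord(
        beta_meta=beta_meta,
        se_meta=se_meta,
        p_meta=float(stats.chi2.sf(z2, df=1)),
        Q=Q,
        p_het=p_het,
        k=k,
    )


def joint_2df_meta(inputs: Sequence[tuple]) -> Meta2dfRecord:
    """GLS combination of per-study (b, V) pairs, b a 2-vector, V its 2x2
    covariance: V_meta = (sum V_k^-1)^-1, b_meta = V_meta sum V_k^-1 b_k."""
    if len(inputs) == 0:
        raise ValueError("no studies to combine")
    precision = np.zeros((2, 2))
    score = np.zeros(2)
    for b, V in inputs:
        b = np.asarray(b, dtype=float)
        V = np.asarray(V, dtype=float)
        Vinv = np.linalg.inv(V)
        precision += Vinv
        score += Vinv @ b
    V_meta = np.linalg.inv(precision)
    b_meta = V_meta @ score
    chi2, p = joint_2df_stat(b_meta, V_meta)
    return Meta2dfRecord(b_meta=b_meta, V_meta=V_meta, chi2_2df=chi2, p_2df=p)


def mean_chi2_test(chi2_values) -> tuple:
    """Mean of k independent 1df chi-squares and the p-value of their sum
    against the chi-square(k) reference (tests mean > 1)."""
    x = np.asarray(chi2_values, dtype=float)
    if x.size == 0:
        raise ValueError("empty chi-square list")
    if np.any(x < 0):
        raise ValueError("chi-square values must be non-negative")
    return float(x.mean()), float(stats.chi2.sf(x.sum(), df=x.size))


# ---------------------------------------------------------------------------
# table-level combination
# ---------------------------------------------------------------------------

def _key(row) -> tuple:
    return (row["CHR"], row["POS"], tuple(sorted((row["EA"], row["NEA"]))))


def _harmonised(ref_row, row):
    """Return row's betas aligned to ref_row's effect allele, or None if the
    variant is palindromic or the alleles are incompatible."""
    if (row["EA"], row["NEA"]) in _PALINDROMIC:
        return None
    if row["EA"] == ref_row["EA"] and row["NEA"] == ref_row["NEA"]:
        return row, 1.0
    if row["EA"] == ref_row["NEA"] and row["NEA"] == ref_row["EA"]:
        flipped = row.copy()
        for col in ("BETA_MARG", "BETA_MAIN", "BETA_INT"):
            flipped[col] = -row[col]
        flipped["EAF"] = 1.0 - row["EAF"]
        flipped["EA"], flipped["NEA"] = ref_row["EA"], ref_row["NEA"]
        return flipped, -1.0
    return None


def _combine_rows(rows: list) -> dict:
    """IVW the marginal and interaction coefficients and GLS the
    (main, interaction) pair across aligned rows of the dialect."""
    marg = ivw_meta([(r["BETA_MARG"], r["SE_MARG"]) for r in rows])
    inter = ivw_meta([(r["BETA_INT"], r["SE_INT"]) for r in rows])
    joint = joint_2df_meta(
        [
            (
                np.array([r["BETA_MAIN"], r["BETA_INT"]]),
                np.array(
                    [
                        [r["SE_MAIN"] ** 2, r["COV_MAIN_INT"]],
                        [r["COV_MAIN_INT"], r["SE_INT"] ** 2],
                    ]
                ),
            )
            for r in rows
        ]
    )
    first = rows[0]
    return {
        "SNPID": first["SNPID"],
        "CHR": first["CHR"],
        "POS": first["POS"],
        "EA": first["EA"],
        "NEA": first["NEA"],
        "EAF": float(np.mean([r["EAF"] for r in rows])),
        "N": int(np.sum([r["N"] for r in rows])),
        "BETA_MARG": marg.beta_meta,
        "SE_MARG": marg.se_meta,
        "BETA_MAIN": float(joint.b_meta[0]),
        "SE_MAIN": float(np.sqrt(joint.V_meta[0, 0])),
        # interaction coefficient reported from the 1df IVW scheme; the GLS
        # joint estimate of it is known to be bias-prone under cross-study
        # heterogeneity (see the bias_sim module)
        "BETA_INT": inter.beta_meta,
        "SE_INT": inter.se_meta,
        "COV_MAIN_INT": float(joint.V_meta[0, 1]),
        "P_1DF": inter.p_meta,
        "P_2DF": joint.p_2df,
        "Q_HET": inter.Q,
        "P_HET": inter.p_het if inter.p_het is not None else np.nan,
    }


def meta_sumstats(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-SNP meta-analysis of several cohort-level summary tables.

    SNPs are keyed by (chr, pos, sorted allele pair); alleles are
    harmonised to the first table carrying the SNP.  Strand-ambiguous
    palindromic variants and unalignable records are dropped with a logged
    count.  SNPs need not be present in every table.
    """
    if len(tables) == 0:
        raise ValueError("no tables to combine")
    groups: dict = {}
    n_dropped = 0
    for tab in tables:
        for _, row in tab.iterrows():
            if (row["EA"], row["NEA"]) in _PALINDROMIC:
                n_dropped += 1
                continue
            key = _key(row)
            if key not in groups:
                groups[key] = [row]
            else:
                aligned = _harmonised(groups[key][0], row)
                if aligned is None:
                    n_dropped += 1
                    continue
                groups[key].append(aligned[0])
    if n_dropped:
        logger.warning("dropped %d palindromic/unalignable records", n_dropped)
    combined = [_combine_rows(rows) for rows in groups.values()]
    out = pd.DataFrame(combined)
    out.attrs["n_dropped"] = n_dropped
    return out.sort_values(["CHR", "POS"], ignore_index=True)


def combine_stages(stage1: pd.DataFrame, stage2: pd.DataFrame) -> pd.DataFrame:
    """Combine discovery-stage and replication-stage summary tables.

    SNPs present in both stages are meta-analysed (IVW for the 1df
    interaction track, GLS for the 2df joint track); SNPs absent from
    stage 2 pass through the stage-1 values flagged ``stage1-only`` in the
    STAGES column.  Allele mismatches without a valid flip are rejected
    with a logged reason.
    """
    # stage combination keys on position alone so that incompatible allele
    # pairs at one site surface as rejected mismatches rather than silently
    # passing through as stage1-only
    s2_index: dict = {}
    for _, row in stage2.iterrows():
        s2_index[(row["CHR"], row["POS"])] = row
    out_rows = []
    n_rejected = 0
    for _, row in stage1.iterrows():
        key = (row["CHR"], row["POS"])
        if key in s2_index:
            aligned = _harmonised(row, s2_index[key])
            if aligned is None:
                n_rejected += 1
                logger.warning(
                    "rejecting %s: allele mismatch without a valid flip",
                    row["SNPID"],
                )
                continue
            rec = _combine_rows([row, aligned[0]])
            rec["STAGES"] = "both"
        else:
            rec = dict(row)
            rec["STAGES"] = "stage1-only"
        out_rows.append(rec)
    if out_rows:
        out = pd.DataFrame(out_rows).sort_values(["CHR", "POS"], ignore_index=True)
    else:
        out = pd.DataFrame(columns=list(stage1.columns) + ["STAGES"])
    out.attrs["n_rejected"] = n_rejected
    return out
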