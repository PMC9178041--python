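"""LD-score regression: heritability per exposure stratum, partitioned
heritability with annotation enrichment, and between-strata comparisons.

The regression model is E[chi2_j] = intercept + N * sum_c tau_c * l(j,c)
(plain fit: one all-SNPs annotation with l(j) / M scaling so the slope is
h2 directly).  Fits use heteroskedasticity weights 1/max(l_j, 1) — a
simplification of the reference tool's combined weights — and
delete-a-block jackknife standard errors over contiguous SNP blocks
(200 blocks by default).  Enrichment of annotation c is
(h2_c / h2) / (M_c / M); its p-value tests the difference between the
heritability share and the SNP share via the jackknife.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LdscFit",
    "StrataComparison",
    "ldsc_fit",
    "ldsc_partitioned",
    "h2_difference_test",
    "het_filter_sensitivity",
    "enrichment_comparison",
]


@dataclass
class LdscFit:
    intercept: float
    intercept_se: float
    h2: float
    h2_se: float
    n_blocks: int
    M: int
    # partitioned-fit extras (None for the plain fit)
    annot_names: Optional[list] = None
    tau: Optional[np.ndarray] = None
    tau_se: Optional[np.ndarray] = None
    M_c: Optional[np.ndarray] = None
    h2_c: Optional[np.ndarray] = None
    h2_c_se: Optional[np.ndarray] = None
    enrichment: Optional[np.ndarray] = None
    enrichment_se: Optional[np.ndarray] = None
    enrichment_p: Optional[np.ndarray] = None
    bonferroni: Optional[float] = None


def _block_bounds(M: int, n_blocks: int):
    edges = np.linspace(0, M, n_blocks + 1).astype(int)
    return list(zip(edges[:-1], edges[1:]))


def _jackknife_wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, n_blocks: int):
    """WLS coefficients with delete-a-block jackknife replicates.

    Returns (coef, replicates) where replicates is n_blocks x k.
    """
    M, k = X.shape
    if M < n_blocks:
        raise ValueError("need at least as many SNPs as jackknife blocks")
    Xw = X * w[:, None]
    A = X.T @ Xw  # X' W X
    c = Xw.T @ y  # X' W y
    # minimum-norm solve: overlapping annotation sets (e.g. a base
    # annotation plus a partition of it) make the design collinear, but the
    # derived per-annotation heritabilities are invariant to the null space
    coef = np.linalg.lstsq(A, c, rcond=None)[0]
    reps = np.empty((n_blocks, k))
    for i, (lo, hi) in enumerate(_block_bounds(M, n_blocks)):
        Xb = X[lo:hi]
        wb = w[lo:hi]
        Ab = Xb.T @ (Xb * wb[:, None])
        cb = (Xb * wb[:, None]).T @ y[lo:hi]
        reps[i] = np.linalg.lstsq(A - Ab, c - cb, rcond=None)[0]
    return coef, reps


def _jackknife_se(reps: np.ndarray) -> np.ndarray:
    B = reps.shape[0]
    return np.sqrt((B - 1) / B * np.sum((reps - reps.mean(0)) ** 2, axis=0))


def ldsc_fit(
    chi2,
    ld_scores,
    N: int,
    M: Optional[int] = None,
    n_blocks: int = 200,
) -> LdscFit:
    """Plain LD-score regression: chi2 on N*l/M with a free intercept.

    The slope is the total SNP heritability h2.  M defaults to the number
    of SNPs supplied.
    """
    chi2 = np.asarray(chi2, dtype=float)
    l = np.asarray(ld_scores, dtype=float)
    if chi2.shape != l.shape:
        raise ValueError("chi2 and ld_scores must have equal length")
    if M is None:
        M = chi2.size
    if np.ptp(l) == 0:
        raise ValueError(
            "constant LD scores: slope and intercept are not separately identifiable"
        )
    x = N * l / M
    X = np.column_stack([np.ones_like(x), x])
    w = 1.0 / np.maximum(l, 1.0)
    coef, reps = _jackknife_wls(X, chi2, w, n_blocks)
    se = _jackknife_se(reps)
    return LdscFit(
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        h2=float(coef[1]),
        h2_se=float(se[1]),
        n_blocks=n_blocks,
        M=int(M),
    )


def ldsc_partitioned(
    chi2,
    annot_ld_scores: np.ndarray,
    annotations: np.ndarray,
    N: int,
    M: Optional[int] = None,
    n_blocks: int = 200,
    annot_names: Optional[Sequence[str]] = None,
) -> LdscFit:
    """Partitioned LD-score regression with per-annotation coefficients.

    annot_ld_scores (M x C) are the annotation-specific LD scores;
    annotations (M x C) is the binary membership matrix and must include
    the all-SNPs base annotation (a column of ones).  h2_c sums the
    per-SNP heritability over annotation members; enrichment is the
    heritability share over the SNP share.
    """
    chi2 = np.asarray(chi2, dtype=float)
    L = np.asarray(annot_ld_scores, dtype=float)
    A = np.asarray(annotations, dtype=float)
    Msnp, C = A.shape
    if M is None:
        M = Msnp
    M_c = A.sum(axis=0)
    if np.any(M_c == 0):
        raise ValueError("annotation with zero SNPs")
    base = np.where(M_c == Msnp)[0]
    if base.size == 0:
        raise ValueError("the all-SNPs base annotation is required")
    if annot_names is None:
        annot_names = [f"annot{c}" for c in range(C)]

    X = np.column_stack([np.ones(Msnp), N * L])
    l_tot = L.sum(axis=1)
    w = 1.0 / np.maximum(l_tot, 1.0)
    coef, reps = _jackknife_wls(X, chi2, w, n_blocks)

    # h2_c(tau) = sum_{j in c} sum_c' tau_c' a_jc' = (A' A tau)_c, linear in tau
    S = A.T @ A  # C x C

    def derived(tau):
        h2_c = S @ tau
        h2_tot = h2_c[base[0]]
        enr = (h2_c / h2_tot) / (M_c / Msnp)
        share_diff = h2_c / h2_tot - M_c / Msnp
        return h2_tot, h2_c, enr, share_diff

    h2_tot, h2_c, enr, share_diff = derived(coef[1:])
    rep_derived = np.array(
        [np.concatenate([[derived(r[1:])[0]], derived(r[1:])[1],
                         derived(r[1:])[2], derived(r[1:])[3]])
         for r in reps]
    )
    se_all = _jackknife_se(rep_derived)
    h2_se = se_all[0]
    h2_c_se = se_all[1 : 1 + C]
    enr_se = se_all[1 + C : 1 + 2 * C]
    diff_se = se_all[1 + 2 * C :]
    coef_se = _jackknife_se(reps)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = share_diff / diff_se
    enr_p = 2.0 * stats.norm.sf(np.abs(z))
    enr_p[base] = np.nan  # the base annotation's enrichment is identically 1

    n_tests = C - base.size
    return LdscFit(
        intercept=float(coef[0]),
        intercept_se=float(coef_se[0]),
        h2=float(h2_tot),
        h2_se=float(h2_se),
        n_blocks=n_blocks,
        M=int(M),
        annot_names=list(annot_names),
        tau=coef[1:],
        tau_se=coef_se[1:],
        M_c=M_c,
        h2_c=h2_c,
        h2_c_se=h2_c_se,
        enrichment=enr,
        enrichment_se=enr_se,
        enrichment_p=enr_p,
        bonferroni=0.05 / n_tests if n_tests > 0 else None,
    )


def h2_difference_test(h2_a: float, se_a: float, h2_b: float, se_b: float) -> tuple:
    """Wald test of equal heritability in two independent strata."""
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    z = (h2_a - h2_b) / np.sqrt(se_a**2 + se_b**2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def het_filter_sensitivity(
    chi2,
    ld_scores,
    p_het,
    N: int,
    thresholds: Sequence[float] = (0.0, 1e-6, 1e-4, 1e-2, 0.05),
    n_blocks: int = 200,
    M: Optional[int] = None,
) -> pd.DataFrame:
    """Heritability after filtering SNPs by heterogeneity p-value.

    For each threshold t, SNPs with p_het < t are dropped and the plain
    fit is recomputed (M held at the full SNP count).  The ``selected``
    column marks the recommended estimate: the largest retained-M fit
    whose intercept lies within 2 jackknife SEs of 1 (falling back to the
    largest retained-M fit if none qualifies).
    """
    chi2 = np.asarray(chi2, dtype=float)
    l = np.asarray(ld_scores, dtype=float)
    ph = np.asarray(p_het, dtype=float)
    if M is None:
        M = chi2.size
    rows = []
    for t in thresholds:
        keep = ~(ph < t)  # NaN p_het (single-study SNPs) is never filtered
        if keep.sum() == 0:
            raise ValueError(f"threshold {t} filters out every SNP")
        fit = ldsc_fit(chi2[keep], l[keep], N=N, M=M,
                       n_blocks=min(n_blocks, int(keep.sum())))
        rows.append(
            {
                "threshold": t,
                "M_kept": int(keep.sum()),
                "h2": fit.h2,
                "h2_se": fit.h2_se,
                "intercept": fit.intercept,
                "intercept_se": fit.intercept_se,
            }
        )
    out = pd.DataFrame(rows)
    good = np.abs(out["intercept"] - 1.0) <= 2.0 * out["intercept_se"]
    pool = out[good] if good.any() else out
    chosen = pool["M_kept"].idxmax()
    out["selected"] = False
    out.loc[chosen, "selected"] = True
    return out


@dataclass
class StrataComparison:
    delta_enrichment: Dict[str, float]  # median(unexposed) - median(exposed)
    prop_nominal: float  # pooled share of annotation tests with p < 0.05
    enrichment_corr: float
    corr_p: float


def enrichment_comparison(
    fit_unexposed: LdscFit,
    fit_exposed: LdscFit,
    grouping: Dict[str, str],
) -> StrataComparison:
    """Compare annotation enrichment between exposure strata.

    grouping maps annotation names to groups (e.g. tissues); per group the
    difference of median enrichments (unexposed minus exposed) is
    reported.  The all-SNPs base annotation (enrichment identically 1) is
    excluded from the correlation and the nominal-significance pool.
    """
    for fit in (fit_unexposed, fit_exposed):
        if fit.annot_names is None:
            raise ValueError("both fits must be partitioned (annotated)")
    shared = [n for n in fit_unexposed.annot_names if n in fit_exposed.annot_names]
    if not shared:
        raise ValueError("no shared annotations between the fits")
    iu = {n: i for i, n in enumerate(fit_unexposed.annot_names)}
    ie = {n: i for i, n in enumerate(fit_exposed.annot_names)}
    non_base = [
        n for n in shared
        if fit_unexposed.M_c[iu[n]] < fit_unexposed.M
        or fit_exposed.M_c[ie[n]] < fit_exposed.M
    ]

    delta: Dict[str, float] = {}
    groups = {grouping[n] for n in non_base if n in grouping}
    for g in sorted(groups):
        members = [n for n in non_base if grouping.get(n) == g]
        eu = np.median([fit_unexposed.enrichment[iu[n]] for n in members])
        ee = np.median([fit_exposed.enrichment[ie[n]] for n in members])
        delta[g] = float(eu - ee)

    ps = np.concatenate(
        [
            [fit_unexposed.enrichment_p[iu[n]] for n in non_base],
            [fit_exposed.enrichment_p[ie[n]] for n in non_base],
        ]
    )
    ps = ps[~np.isnan(ps)]
    prop = float(np.mean(ps < 0.05)) if ps.size else np.nan

    eu = np.array([fit_unexposed.enrichment[iu[n]] for n in non_base])
    ee = np.array([fit_exposed.enrichment[ie[n]] for n in non_base])
    if eu.size >= 2 and np.std(eu) > 0 and np.std(ee) > 0:
        r, rp = stats.pearsonr(eu, ee)
    else:
        r, rp = (1.0, np.nan) if eu.size and np.allclose(eu, ee) else (np.nan, np.nan)
    return StrataComparison(
        delta_enrichment=delta,
        prop_nominal=prop,
        enrichment_corr=float(r),
        corr_p=float(rp) if rp is not None else np.nan,
    )
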