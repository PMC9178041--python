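"""Interaction-effect enrichment conditional on marginal effects.

Given pre-clumped (independent) SNPs, these tools ask whether SNPs with
strong marginal genetic association carry more nominally significant
interaction effects than the 5% expected by chance (binned proportions
with Wilson score bands), whether interaction and marginal effect
directions are in disequilibrium within a phenotype-exposure-ancestry
trio (exact binomial sign test), whether flagged trios accumulate across
many trios (one-sided exact binomial tail), and whether a SNP set carries
aggregate interaction signal (omnibus chi-square, unweighted and weighted
genetic-risk-score tests on summary statistics).

All binomial tails are exact, never normal approximations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentBin",
    "TrioClassification",
    "wilson_interval",
    "marginal_bins_enrichment",
    "classify_directions",
    "cross_trio_enrichment",
    "set_interaction_tests",
]

DEFAULT_BIN_EDGES = (1.0, 0.1, 0.01, 1e-3, 1e-4, 1e-5, 1e-6)


@dataclass
class EnrichmentBin:
    """Proportion of interaction-significant SNPs in one marginal-p bin.

    The (upper, lower] interval is on the marginal p-value; the Wilson
    bands are the null reference bands around alpha_int given n_snps, at
    band levels 0.05 and 1e-4, plus the Wilson CI of the observed
    proportion itself.
    """

    upper: float
    lower: float
    n_snps: int
    n_int_sig: int
    proportion: float  # NaN when the bin is empty
    ci_low: float
    ci_high: float
    null_band_05: tuple
    null_band_1e4: tuple


def wilson_interval(x: int, n: int, alpha: float = 0.05) -> tuple:
    """Wilson score confidence interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    z = stats.norm.isf(alpha / 2.0)
    phat = x / n
    denom = 1.0 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2))
    lo = 0.0 if x == 0 else max(0.0, centre - half)
    hi = 1.0 if x == n else min(1.0, centre + half)
    return (lo, hi)


def _null_band(n: int, alpha_int: float, band_alpha: float) -> tuple:
    """Wilson band around the null proportion alpha_int for n SNPs."""
    if n == 0:
        return (np.nan, np.nan)
    return wilson_interval(int(round(alpha_int * n)), n, band_alpha)


def marginal_bins_enrichment(
    marg_p,
    int_p,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    alpha_int: float = 0.05,
    cumulative: bool = False,
) -> List[EnrichmentBin]:
    """Proportion of interaction p < alpha_int per marginal-p bin.

    Inputs must be pre-clumped so SNPs are independent.  Disjoint mode
    bins marg_p into (edges[i+1], edges[i]]; cumulative mode uses
    marg_p <= edges[i] (the last edge then plays the role of the
    genome-wide threshold).  Empty bins report proportion NaN.
    """
    marg_p = np.asarray(marg_p, dtype=float)
    int_p = np.asarray(int_p, dtype=float)
    if marg_p.shape != int_p.shape:
        raise ValueError("p-value vectors must have equal length")
    if np.any(marg_p <= 0) or np.any(marg_p > 1) or np.any(int_p <= 0) or np.any(int_p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) >= 0):
        raise ValueError("bin edges must be strictly decreasing")

    bins: List[EnrichmentBin] = []
    if cumulative:
        pairs = [(e, 0.0) for e in edges]
    else:
        pairs = list(zip(edges[:-1], edges[1:])) + [(edges[-1], 0.0)]
    for upper, lower in pairs:
        mask = (marg_p <= upper) & (marg_p > lower)
        n = int(mask.sum())
        x = int((int_p[mask] < alpha_int).sum())
        if n > 0:
            prop = x / n
            ci = wilson_interval(x, n, 0.05)
        else:
            prop, ci = np.nan, (np.nan, np.nan)
        bins.append(
            EnrichmentBin(
                upper=float(upper),
                lower=float(lower),
                n_snps=n,
                n_int_sig=x,
                proportion=prop,
                ci_low=ci[0],
                ci_high=ci[1],
                null_band_05=_null_band(n, alpha_int, 0.05),
                null_band_1e4=_null_band(n, alpha_int, 1e-4),
            )
        )
    return bins


@dataclass
class TrioClassification:
    """Direction concordance of marginal and interaction effects within one
    phenotype-exposure-ancestry trio's significant independent SNPs."""

    trio_id: Optional[tuple]
    n_sig_snps: int
    n_concordant: int
    n_discordant: int
    n_opposite: int
    p_trio: float


def classify_directions(
    records: pd.DataFrame, trio_id: Optional[tuple] = None
) -> TrioClassification:
    """Classify significant SNPs by effect-direction agreement.

    concordant: sign(beta_marginal) == sign(beta_interaction) (enhanced
    genetic effect among the exposed); discordant: opposite signs (reduced
    effect); opposite: the exposed-stratum effect beta_main + beta_int has
    the opposite sign of beta_main (effect reversal between strata).
    Coefficients exactly zero are excluded from the concordance counts.
    p_trio is the two-sided exact binomial test of concordant vs
    discordant against 0.5.
    """
    bm = np.asarray(records["BETA_MARG"], dtype=float)
    bg = np.asarray(records["BETA_MAIN"], dtype=float)
    bge = np.asarray(records["BETA_INT"], dtype=float)
    nonzero = (np.sign(bm) != 0) & (np.sign(bge) != 0)
    conc = int(np.sum(nonzero & (np.sign(bm) == np.sign(bge))))
    disc = int(np.sum(nonzero & (np.sign(bm) != np.sign(bge))))
    exposed = bg + bge
    opp = int(np.sum((np.sign(bg) != 0) & (np.sign(exposed) != 0)
                     & (np.sign(bg) != np.sign(exposed))))
    n_trials = conc + disc
    if n_trials > 0:
        p = stats.binomtest(conc, n_trials, 0.5, alternative="two-sided").pvalue
    else:
        p = 1.0
    return TrioClassification(
        trio_id=trio_id,
        n_sig_snps=len(records),
        n_concordant=conc,
        n_discordant=disc,
        n_opposite=opp,
        p_trio=float(p),
    )


def cross_trio_enrichment(trio_ps, alpha_trio: float = 0.05) -> tuple:
    """Do more trios show direction disequilibrium than chance allows?

    Returns (n_flagged, n_trios, p_binom, bonferroni_threshold) where
    p_binom is the exact one-sided upper binomial tail
    P(X >= n_flagged | n_trios, alpha_trio) and the Bonferroni threshold
    is 0.05 / n_trios.
    """
    p = np.asarray(trio_ps, dtype=float)
    if p.size == 0:
        raise ValueError("empty trio p-value list")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("trio p-values must lie in [0, 1]")
    n_flagged = int(np.sum(p < alpha_trio))
    n_trios = int(p.size)
    p_binom = float(stats.binom.sf(n_flagged - 1, n_trios, alpha_trio))
    return n_flagged, n_trios, p_binom, 0.05 / n_trios


def set_interaction_tests(
    bGE, seGE, mode: str, weights=None
) -> tuple:
    """Aggregate interaction tests on independent SNPs' summary statistics.

    omnibus: sum of squared z against chi-square(k).
    uGRS: z = sum(w*b) / sqrt(sum(w^2 se^2)) with unit weights (alleles
    assumed pre-aligned), two-sided normal p.
    wGRS: same with externally supplied weights (e.g. marginal effects
    from an independent GWAS).
    """
    b = np.asarray(bGE, dtype=float)
    se = np.asarray(seGE, dtype=float)
    if b.size == 0:
        raise ValueError("empty SNP set")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if mode == "omnibus":
        stat = float(np.sum((b / se) ** 2))
        return stat, float(stats.chi2.sf(stat, df=b.size))
    if mode == "uGRS":
        w = np.ones_like(b)
    elif mode == "wGRS":
        if weights is None:
            raise ValueError("wGRS requires external weights")
        w = np.asarray(weights, dtype=float)
        if w.shape != b.shape:
            raise ValueError("weights must match the SNP set")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    z = float(np.sum(w * b) / np.sqrt(np.sum(w**2 * se**2)))
    return z, float(2.0 * stats.norm.sf(abs(z)))


def plot_enrichment(bins: List[EnrichmentBin], ax=None):
    """Proportion of interaction-significant SNPs against the marginal-p
    threshold, with the two null Wilson bands shaded (optional diagnostic;
    requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xs = np.arange(len(bins))
    props = [b.proportion for b in bins]
    ax.fill_between(
        xs,
        [b.null_band_1e4[0] for b in bins],
        [b.null_band_1e4[1] for b in bins],
        color="0.85", label="null band (1e-4)",
    )
    ax.fill_between(
        xs,
        [b.null_band_05[0] for b in bins],
        [b.null_band_05[1] for b in bins],
        color="0.6", label="null band (0.05)",
    )
    ax.plot(xs, props, "o-", color="C0", label="observed")
    ax.axhline(0.05, ls="--", color="k", lw=0.8)
    ax.set_xticks(xs)
    ax.set_xticklabels([f"{b.upper:g}" for b in bins])
    ax.set_xlabel("marginal p-value bin (upper edge)")
    ax.set_ylabel("prop. interaction p < 0.05")
    ax.legend()
    return ax
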