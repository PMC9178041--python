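"""Per-SNP interaction and marginal model fitting; 1df and 2df tests.

The interaction model regressed at every SNP is

    Y = b0 + bG*G + bE*E + bGE*(G*E) + eps

and the marginal model drops the product term.  The 1df test is the Wald
test of bGE; the 2df joint test evaluates (bG, bGE) against zero using
their estimated 2x2 covariance.  For a binary 0/1 exposure the exposed /
unexposed stratum effects are exact linear functions of the interaction
model coefficients (bG and bG + bGE), which is how stratified summary
statistics are derived without refitting.

Fitting is done through closed-form normal equations on sufficient
statistics, batched across SNPs (and across simulation replicates
elsewhere), which is what makes genome-scan-sized null calibrations cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import CohortData

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateDesignError",
    "InteractionFit",
    "MarginalFit",
    "StratumEffects",
    "fit_interaction_model",
    "fit_marginal_model",
    "joint_2df_stat",
    "stratify_effects",
    "run_gwis",
    "batched_interaction_fit",
]


class DegenerateDesignError(ValueError):
    """Raised when the regression design is rank deficient (e.g. everyone
    exposed makes G*E collinear with G, or G is monomorphic)."""


@dataclass
class InteractionFit:
    betaG_hat: float
    betaE_hat: float
    betaGE_hat: float
    cov: np.ndarray  # 2x2 covariance of (betaG_hat, betaGE_hat)
    n: int
    p_1df: float
    chi2_2df: float
    p_2df: float

    @property
    def seG(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))

    @property
    def seGE(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))


@dataclass
class MarginalFit:
    betaM_hat: float
    seM: float
    p_marg: float


@dataclass
class StratumEffects:
    beta_unexposed: float
    se_unexposed: float
    beta_exposed: float
    se_exposed: float


def _check_vectors(*arrays):
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    n = len(arrays[0])
    for a in arrays[1:]:
        if len(a) != n:
            raise ValueError("input vectors must have equal length")
    return arrays


_COND_MAX = 1e12


def _solve_ols(XtX: np.ndarray, XtY: np.ndarray, YtY: float, n: int):
    """Closed-form OLS from sufficient statistics.

    Returns (beta, cov, sigma2, df_resid).  Raises DegenerateDesignError if
    the normal-equation matrix is numerically singular.
    """
    k = XtX.shape[0]
    if np.linalg.cond(XtX) > _COND_MAX:
        raise DegenerateDesignError(
            "design matrix is rank deficient (collinear columns)"
        )
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ XtY
    rss = YtY - beta @ XtY
    df = n - k
    if df <= 0:
        raise DegenerateDesignError(f"need more than {k} observations")
    sigma2 = max(rss / df, 0.0)
    return beta, sigma2 * XtX_inv, sigma2, df


def joint_2df_stat(b, V) -> tuple:
    """Joint chi-square of a 2-vector against zero: chi2 = b' V^-1 b.

    p is the chi-square(2 df) survival probability.
    """
    b = np.asarray(b, dtype=float)
    V = np.asarray(V, dtype=float)
    if np.linalg.cond(V) > _COND_MAX:
        raise np.linalg.LinAlgError("singular covariance in 2df statistic")
    chi2 = float(b @ np.linalg.solve(V, b))
    return chi2, float(stats.chi2.sf(chi2, df=2))


def fit_interaction_model(G, E, Y, robust: bool = False) -> InteractionFit:
    """OLS of Y on (1, G, E, G*E) with the 1df and 2df tests.

    robust=True swaps model-based (homoskedastic) standard errors for the
    HC0 sandwich estimator.
    """
    G, E, Y = _check_vectors(G, E, Y)
    n = len(G)
    if np.ptp(G) == 0:
        raise DegenerateDesignError("G is constant (monomorphic SNP)")
    if np.ptp(E) == 0:
        raise DegenerateDesignError(
            "E is constant: G*E is collinear with G (degenerate design)"
        )
    X = np.column_stack([np.ones(n), G, E, G * E])
    XtX = X.T @ X
    XtY = X.T @ Y
    beta, cov_full, sigma2, df = _solve_ols(XtX, XtY, float(Y @ Y), n)
    if robust:
        resid = Y - X @ beta
        XtX_inv = np.linalg.inv(XtX)
        meat = (X * resid[:, None] ** 2).T @ X
        cov_full = XtX_inv @ meat @ XtX_inv
    cov2 = cov_full[np.ix_([1, 3], [1, 3])]
    if sigma2 > 0 and not robust:
        degenerate_cov = False
    else:
        degenerate_cov = np.linalg.cond(cov2) > _COND_MAX if np.any(cov2) else True
    if degenerate_cov:
        # noiseless data: coefficients are exact, tests saturate
        p_1df = 1.0 if beta[3] == 0 else 0.0
        chi2_2df = 0.0 if not np.any(beta[[1, 3]]) else np.inf
        p_2df = 1.0 if chi2_2df == 0.0 else 0.0
    else:
        z2 = beta[3] ** 2 / cov2[1, 1]
        p_1df = float(stats.chi2.sf(z2, df=1))
        chi2_2df, p_2df = joint_2df_stat(beta[[1, 3]], cov2)
    return InteractionFit(
        betaG_hat=float(beta[1]),
        betaE_hat=float(beta[2]),
        betaGE_hat=float(beta[3]),
        cov=cov2,
        n=n,
        p_1df=p_1df,
        chi2_2df=chi2_2df,
        p_2df=p_2df,
    )


def fit_marginal_model(G, E, Y) -> MarginalFit:
    """OLS of Y on (1, G, E): the marginal genetic effect, exposure-adjusted
    but not interaction-modelled."""
    G, E, Y = _check_vectors(G, E, Y)
    n = len(G)
    if np.ptp(G) == 0:
        raise DegenerateDesignError("G is constant (monomorphic SNP)")
    X = np.column_stack([np.ones(n), G, E])
    beta, cov, _, _ = _solve_ols(X.T @ X, X.T @ Y, float(Y @ Y), n)
    se = float(np.sqrt(cov[1, 1]))
    if se == 0:  # noiseless fit
        p = 1.0 if beta[1] == 0 else 0.0
    else:
        p = float(stats.chi2.sf((beta[1] / se) ** 2, df=1))
    return MarginalFit(betaM_hat=float(beta[1]), seM=se, p_marg=p)


def stratify_effects(fit: InteractionFit) -> StratumEffects:
    """Exposure-stratum genetic effects from the interaction model (binary
    0/1 exposure): unexposed = bG, exposed = bG + bGE with variance
    var(bG) + var(bGE) + 2 cov."""
    var_exp = fit.cov[0, 0] + fit.cov[1, 1] + 2.0 * fit.cov[0, 1]
    if var_exp < 0:
        raise ValueError(
            "implied exposed-stratum variance is negative: invalid covariance input"
        )
    return StratumEffects(
        beta_unexposed=fit.betaG_hat,
        se_unexposed=fit.seG,
        beta_exposed=fit.betaG_hat + fit.betaGE_hat,
        se_exposed=float(np.sqrt(var_exp)),
    )


# ---------------------------------------------------------------------------
# batched fitting across SNP (or replicate) columns
# ---------------------------------------------------------------------------

def batched_interaction_fit(G: np.ndarray, E: np.ndarray, Y: np.ndarray) -> dict:
    """Vectorised interaction-model OLS across columns.

    G: n x m matrix (one column per SNP or replicate).  E and Y may be
    length-n vectors shared across columns or n x m matrices.  Returns a
    dict of length-m arrays: betaG, betaE, betaGE, varG, varGE, covG_GE,
    sigma2, plus a boolean mask ``ok`` flagging columns whose design was
    non-degenerate (others carry NaN).

    Also fits the marginal model on (1, G, E), returning betaM / varM.
    """
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    E = np.asarray(E, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Em = E if E.ndim == 2 else np.broadcast_to(E[:, None], (n, m))
    Ym = Y if Y.ndim == 2 else np.broadcast_to(Y[:, None], (n, m))

    GE = G * Em
    # column sums of all products needed for X'X, X'Y with X = [1, G, E, GE]
    sG = G.sum(0)
    sE = Em.sum(0)
    sGE = GE.sum(0)
    sGG = (G * G).sum(0)
    sEE = (Em * Em).sum(0)
    sGGE = (G * GE).sum(0)
    sGEE = (GE * Em).sum(0)
    sGEGE = (GE * GE).sum(0)
    sY = Ym.sum(0)
    sGY = (G * Ym).sum(0)
    sEY = (Em * Ym).sum(0)
    sGEY = (GE * Ym).sum(0)
    sYY = (Ym * Ym).sum(0)

    XtX = np.empty((m, 4, 4))
    XtX[:, 0, 0] = n
    XtX[:, 0, 1] = XtX[:, 1, 0] = sG
    XtX[:, 0, 2] = XtX[:, 2, 0] = sE
    XtX[:, 0, 3] = XtX[:, 3, 0] = sGE
    XtX[:, 1, 1] = sGG
    XtX[:, 1, 2] = XtX[:, 2, 1] = sGE
    XtX[:, 1, 3] = XtX[:, 3, 1] = sGGE
    XtX[:, 2, 2] = sEE
    XtX[:, 2, 3] = XtX[:, 3, 2] = sGEE
    XtX[:, 3, 3] = sGEGE
    XtY = np.stack([sY, sGY, sEY, sGEY], axis=1)

    ok = (np.ptp(G, axis=0) > 0) & (np.ptp(Em, axis=0) > 0)
    # guard against exactly singular designs that survive the ptp screen
    with np.errstate(all="ignore"):
        dets = np.linalg.det(XtX)
    ok &= np.isfinite(dets) & (np.abs(dets) > 1e-300)

    out = {
        k: np.full(m, np.nan)
        for k in (
            "betaG", "betaE", "betaGE", "varG", "varGE", "covG_GE",
            "sigma2", "betaM", "varM",
        )
    }
    out["ok"] = ok
    if ok.any():
        idx = np.where(ok)[0]
        XtX_inv = np.linalg.inv(XtX[idx])
        beta = np.einsum("kij,kj->ki", XtX_inv, XtY[idx])
        rss = sYY[idx] - np.einsum("ki,ki->k", beta, XtY[idx])
        sigma2 = np.maximum(rss / (n - 4), 0.0)
        out["betaG"][idx] = beta[:, 1]
        out["betaE"][idx] = beta[:, 2]
        out["betaGE"][idx] = beta[:, 3]
        out["varG"][idx] = sigma2 * XtX_inv[:, 1, 1]
        out["varGE"][idx] = sigma2 * XtX_inv[:, 3, 3]
        out["covG_GE"][idx] = sigma2 * XtX_inv[:, 1, 3]
        out["sigma2"][idx] = sigma2

        # marginal model on the 3x3 leading principal submatrix
        XtX3 = XtX[np.ix_(idx, [0, 1, 2], [0, 1, 2])]
        XtY3 = XtY[np.ix_(idx, [0, 1, 2])]
        XtX3_inv = np.linalg.inv(XtX3)
        beta3 = np.einsum("kij,kj->ki", XtX3_inv, XtY3)
        rss3 = sYY[idx] - np.einsum("ki,ki->k", beta3, XtY3)
        s2m = np.maximum(rss3 / (n - 3), 0.0)
        out["betaM"][idx] = beta3[:, 1]
        out["varM"][idx] = s2m * XtX3_inv[:, 1, 1]
    return out


def batched_2df(betaG, betaGE, varG, varGE, covG_GE):
    """Vectorised 2df joint statistic b' V^-1 b and its chi2(2) p-value."""
    det = varG * varGE - covG_GE**2
    chi2 = (
        betaG**2 * varGE - 2.0 * betaG * betaGE * covG_GE + betaGE**2 * varG
    ) / det
    return chi2, stats.chi2.sf(chi2, df=2)


def run_gwis(
    cohort: CohortData,
    snp_meta: Optional[pd.DataFrame] = None,
    pos_spacing: int = 10_000,
) -> pd.DataFrame:
    """Genome-wide interaction scan over every SNP of one cohort.

    Returns one summary-statistic row per polymorphic SNP (the on-disk
    dialect of :mod:`gxemeta.sumstats`); monomorphic or otherwise degenerate
    SNPs are excluded with a logged reason and listed in
    ``result.attrs["excluded"]``.

    snp_meta optionally supplies SNPID/CHR/POS/EA/NEA columns; by default
    SNPs are laid on chromosome 1 at ``pos_spacing`` intervals.
    """
    G = cohort.genotypes
    n, m = G.shape
    if snp_meta is None:
        snp_meta = pd.DataFrame(
            {
                "SNPID": [f"snp{j + 1:06d}" for j in range(m)],
                "CHR": 1,
                "POS": (np.arange(m) + 1) * pos_spacing,
                "EA": "A",
                "NEA": "G",
            }
        )
    fits = batched_interaction_fit(G, cohort.exposure, cohort.phenotype)
    ok = fits["ok"]
    excluded = [
        (snp_meta["SNPID"].iloc[j], "monomorphic or degenerate design")
        for j in np.where(~ok)[0]
    ]
    for snp_id, reason in excluded:
        logger.info("excluding %s: %s", snp_id, reason)

    idx = np.where(ok)[0]
    seG = np.sqrt(fits["varG"][idx])
    seGE = np.sqrt(fits["varGE"][idx])
    seM = np.sqrt(fits["varM"][idx])
    z1 = fits["betaGE"][idx] / seGE
    chi2_2df, p_2df = batched_2df(
        fits["betaG"][idx],
        fits["betaGE"][idx],
        fits["varG"][idx],
        fits["varGE"][idx],
        fits["covG_GE"][idx],
    )
    eaf = G[:, idx].mean(axis=0) / 2.0
    df = pd.DataFrame(
        {
            "SNPID": snp_meta["SNPID"].to_numpy()[idx],
            "CHR": snp_meta["CHR"].to_numpy()[idx],
            "POS": snp_meta["POS"].to_numpy()[idx],
            "EA": snp_meta["EA"].to_numpy()[idx],
            "NEA": snp_meta["NEA"].to_numpy()[idx],
            "EAF": eaf,
            "N": n,
            "BETA_MARG": fits["betaM"][idx],
            "SE_MARG": seM,
            "BETA_MAIN": fits["betaG"][idx],
            "SE_MAIN": seG,
            "BETA_INT": fits["betaGE"][idx],
            "SE_INT": seGE,
            "COV_MAIN_INT": fits["covG_GE"][idx],
            "P_1DF": stats.chi2.sf(z1**2, df=1),
            "P_2DF": p_2df,
            "Q_HET": np.nan,
            "P_HET": np.nan,
        }
    )
    df.attrs["excluded"] = excluded
    return df
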