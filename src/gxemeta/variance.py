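"""Phenotypic variance explained at top SNPs, from summary statistics.

With genotype G ~ Binomial(2, f) under HWE, exposure E independent of G,
and independent (pre-clumped) SNPs, the variance of the fitted genetic
predictor decomposes per SNP as

    marginal:  betaM^2 * var(G)
    joint:     betaG^2 var(G) + betaGE^2 var(GE) + 2 betaG betaGE cov(G, GE)

and the interaction component is reported as joint - marginal (floored at
zero with a flag when sampling noise drives it negative); the pure
interaction term sum(betaGE^2 var(GE)) is reported alongside.  The
significance of the interaction component uses the chi-square
approximation to the joint test of all interaction coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SnpMoments",
    "VarianceDecomposition",
    "snp_interaction_moments",
    "variance_decomposition",
    "interaction_joint_test",
]


@dataclass
class SnpMoments:
    f: float
    muG: float
    varG: float
    varGE: float
    covG_GE: float
    exposure_kind: str
    exposure_param: Union[float, tuple]


def snp_interaction_moments(f: float, exposure_param, kind: str) -> SnpMoments:
    """Moments of G, G*E and their covariance under HWE and G independent
    of E.

    Binary E (prevalence p):   var(GE) = p(varG + muG^2) - p^2 muG^2,
                               cov(G, GE) = p varG.
    Continuous E (mu, var):    var(GE) = varG(var + mu^2) + muG^2 var,
                               cov(G, GE) = mu varG.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("allele frequency must lie in (0, 1)")
    muG = 2.0 * f
    varG = 2.0 * f * (1.0 - f)
    if kind == "binary":
        p = float(exposure_param)
        if not 0.0 <= p <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        varGE = p * (varG + muG**2) - p**2 * muG**2
        cov = p * varG
    elif kind == "continuous":
        mu, var = exposure_param
        if var < 0:
            raise ValueError("exposure variance must be >= 0")
        varGE = varG * (var + mu**2) + muG**2 * var
        cov = mu * varG
    else:
        raise ValueError(f"unknown exposure kind {kind!r}")
    return SnpMoments(
        f=f, muG=muG, varG=varG, varGE=varGE, covG_GE=cov,
        exposure_kind=kind, exposure_param=exposure_param,
    )


@dataclass
class VarianceDecomposition:
    r2_marginal: float
    r2_joint: float
    r2_interaction: float
    r2_interaction_pure: float
    p_interaction_joint: float
    n_snps: int
    floored: bool  # True when joint - marginal was negative and clipped
    convention: str = "joint-minus-marginal"


def interaction_joint_test(bGE, seGE) -> float:
    """Approximate joint significance of all interaction coefficients:
    sum of squared z against chi-square(k), SNPs assumed independent."""
    b = np.asarray(bGE, dtype=float)
    se = np.asarray(seGE, dtype=float)
    if b.size == 0:
        raise ValueError("empty SNP set")
    stat = np.sum((b / se) ** 2)
    return float(stats.chi2.sf(stat, df=b.size))


def variance_decomposition(
    records: pd.DataFrame,
    exposure_param,
    kind: str = "binary",
    var_Y: float = 1.0,
) -> VarianceDecomposition:
    """Decompose variance explained by top independent SNPs.

    records must carry BETA_MARG, BETA_MAIN, BETA_INT, SE_INT and EAF;
    var_Y is the phenotypic variance (1 for standardized traits).
    """
    if len(records) == 0:
        raise ValueError("empty SNP set")
    if var_Y <= 0:
        raise ValueError("var_Y must be positive")
    r2_marg = 0.0
    r2_joint = 0.0
    r2_pure = 0.0
    for _, r in records.iterrows():
        mom = snp_interaction_moments(float(r["EAF"]), exposure_param, kind)
        r2_marg += r["BETA_MARG"] ** 2 * mom.varG
        r2_joint += (
            r["BETA_MAIN"] ** 2 * mom.varG
            + r["BETA_INT"] ** 2 * mom.varGE
            + 2.0 * r["BETA_MAIN"] * r["BETA_INT"] * mom.covG_GE
        )
        r2_pure += r["BETA_INT"] ** 2 * mom.varGE
    r2_marg /= var_Y
    r2_joint /= var_Y
    r2_pure /= var_Y
    diff = r2_joint - r2_marg
    floored = diff < 0
    p_joint = interaction_joint_test(
        records["BETA_INT"].to_numpy(), records["SE_INT"].to_numpy()
    )
    return VarianceDecomposition(
        r2_marginal=r2_marg,
        r2_joint=r2_joint,
        r2_interaction=max(diff, 0.0),
        r2_interaction_pure=r2_pure,
        p_interaction_joint=p_joint,
        n_snps=len(records),
        floored=bool(floored),
    )
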