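"""Synthetic multi-cohort genotype/exposure/phenotype generator.

Emulates the data structure a gene-lifestyle interaction GWAS consumes:
Hardy-Weinberg genotypes with block LD (Gaussian copula), binary or
continuous exposures with cohort-specific prevalence/mean, phenotypes from
a linear interaction model

    Y = b0 + bG*G + bE*E + bGE*G*E + eps,   eps ~ N(0, sigma2),

with cohort-heterogeneous coefficients, and LD-score / annotation inputs
for heritability regression.

All randomness flows from a single integer seed per cohort spec; sub-streams
(genotypes, exposure, residual noise) are spawned with fixed offsets so
outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

__all__ = [
    "PhenoModel",
    "CohortSpec",
    "CohortData",
    "LdscSimSpec",
    "simulate_genotypes",
    "simulate_exposure",
    "simulate_phenotype",
    "simulate_cohort",
    "simulate_cohorts",
    "simulate_ldsc_sumstats",
    "simulate_ldsc_inputs",
    "write_cohort_tsv",
]

# fixed offsets for per-purpose substreams derived from the master seed
_GENO_STREAM = 0
_EXPO_STREAM = 1
_NOISE_STREAM = 2


@dataclass(frozen=True)
class PhenoModel:
    """Coefficients of the linear interaction model.

    beta0: intercept (trait units); betaG: genetic main effect at E=0
    (per effect allele); betaE: exposure effect; betaGE: interaction effect
    (per allele per exposure unit); sigma2: residual variance.
    """

    beta0: float = 0.0
    betaG: float = 0.0
    betaE: float = 0.0
    betaGE: float = 0.0
    sigma2: float = 1.0

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")


MafSpec = Union[float, tuple, Sequence[float], np.ndarray]


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of one cohort.

    maf: a scalar effect-allele frequency, a (low, high) sampling range,
    or a length-m array of per-SNP frequencies.
    ld_blocks: list of (block_size, rho) consumed left to right along the
    SNP axis; SNPs not covered by any block are independent.
    exposure_param: prevalence p for a binary exposure, (mean, variance)
    for a continuous one.
    """

    n: int
    m: int
    maf: MafSpec = (0.05, 0.5)
    ld_blocks: tuple = ()
    exposure_kind: str = "binary"
    exposure_param: Union[float, tuple] = 0.5
    model: PhenoModel = field(default_factory=PhenoModel)
    seed: int = 0

    def __post_init__(self):
        if self.n < 1 or self.m < 1:
            raise ValueError("n and m must be >= 1")
        if self.exposure_kind not in ("binary", "continuous"):
            raise ValueError(f"unknown exposure_kind {self.exposure_kind!r}")
        if self.exposure_kind == "binary":
            p = float(self.exposure_param)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence must be in [0, 1], got {p}")
        else:
            mu, var = self.exposure_param
            if var < 0:
                raise ValueError("exposure variance must be >= 0")
        total = sum(int(b) for b, _ in self.ld_blocks)
        if total > self.m:
            raise ValueError("ld_blocks cover more SNPs than m")
        for _, rho in self.ld_blocks:
            if not 0.0 <= rho < 1.0:
                raise ValueError(f"block correlation must be in [0, 1), got {rho}")

    def freqs(self) -> np.ndarray:
        """Per-SNP effect-allele frequencies, resolved deterministically."""
        if np.isscalar(self.maf):
            f = np.full(self.m, float(self.maf))
        elif isinstance(self.maf, tuple) and len(self.maf) == 2 and np.isscalar(self.maf[0]):
            lo, hi = self.maf
            rng = np.random.default_rng([self.seed, 9001])
            f = rng.uniform(lo, hi, size=self.m)
        else:
            f = np.asarray(self.maf, dtype=float)
            if f.shape != (self.m,):
                raise ValueError("per-SNP maf array must have length m")
        if np.any(f <= 0) or np.any(f >= 1):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        return f


@dataclass
class CohortData:
    """Individual-level data for one cohort with its generative truth."""

    genotypes: np.ndarray  # n x m dosages in {0, 1, 2}
    exposure: np.ndarray  # length n
    phenotype: np.ndarray  # length n
    truth: CohortSpec

    def __post_init__(self):
        n, m = self.genotypes.shape
        if len(self.exposure) != n or len(self.phenotype) != n:
            raise ValueError("inconsistent array dimensions")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def simulate_genotypes(spec: CohortSpec) -> np.ndarray:
    """Draw an n x m dosage matrix under HWE with block LD.

    Each SNP's dosage is produced by double-thresholding a standard normal
    latent variable at the HWE genotype cumulative probabilities
    ((1-f)^2 and 1-f^2), so marginals are exactly HWE.  Within an LD block
    latents share an equicorrelation rho (one common factor), giving
    tunable positive dosage correlation; across blocks latents are
    independent.
    """
    rng = _rng(spec.seed, _GENO_STREAM)
    f = spec.freqs()
    n, m = spec.n, spec.m

    # latent standard normals with block equicorrelation
    z = rng.standard_normal((n, m))
    col = 0
    for size, rho in spec.ld_blocks:
        size = int(size)
        if rho > 0:
            shared = rng.standard_normal((n, 1))
            z[:, col : col + size] = (
                np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * z[:, col : col + size]
            )
        col += size

    # double threshold: P(G=0) = (1-f)^2, P(G<=1) = 1 - f^2
    q0 = stats.norm.ppf((1.0 - f) ** 2)
    q1 = stats.norm.ppf(1.0 - f**2)
    dosage = (z > q0).astype(np.int8) + (z > q1).astype(np.int8)
    return dosage.astype(float)


def simulate_exposure(spec: CohortSpec) -> np.ndarray:
    """Draw the exposure vector: Bernoulli(p) or Normal(mean, variance)."""
    rng = _rng(spec.seed, _EXPO_STREAM)
    if spec.exposure_kind == "binary":
        p = float(spec.exposure_param)
        return rng.binomial(1, p, size=spec.n).astype(float)
    mu, var = spec.exposure_param
    return rng.normal(mu, np.sqrt(var), size=spec.n)


def simulate_phenotype(
    genotypes: np.ndarray,
    exposure: np.ndarray,
    model: PhenoModel,
    causal_index: Optional[int] = 0,
    seed: int = 0,
) -> np.ndarray:
    """Phenotype from the linear interaction model at one causal SNP.

    Non-causal SNPs contribute nothing.  causal_index=None yields a pure
    exposure + noise trait (a global null for the genetic tests).
    """
    n, m = genotypes.shape
    if len(exposure) != n:
        raise ValueError("exposure length does not match genotypes")
    rng = _rng(seed, _NOISE_STREAM)
    y = model.beta0 + model.betaE * exposure
    if causal_index is not None:
        if not 0 <= causal_index < m:
            raise IndexError(f"causal_index {causal_index} out of range for m={m}")
        g = genotypes[:, causal_index]
        y = y + model.betaG * g + model.betaGE * g * exposure
    if model.sigma2 > 0:
        y = y + rng.normal(0.0, np.sqrt(model.sigma2), size=n)
    return y


def simulate_cohort(spec: CohortSpec, causal_index: Optional[int] = 0) -> CohortData:
    """Generate one internally consistent cohort."""
    g = simulate_genotypes(spec)
    e = simulate_exposure(spec)
    y = simulate_phenotype(g, e, spec.model, causal_index=causal_index, seed=spec.seed)
    return CohortData(genotypes=g, exposure=e, phenotype=y, truth=spec)


def simulate_cohorts(
    specs: Sequence[CohortSpec], causal_index: Optional[int] = 0
) -> list:
    """Generate independent cohorts; specs may differ in any field.

    Cross-cohort heterogeneity in the genetic main effect and in exposure
    prevalence — the knobs behind 2df meta-analysis bias — is expressed by
    giving the specs different ``model.betaG`` / ``exposure_param``.
    """
    if len(specs) == 0:
        raise ValueError("at least one cohort spec is required")
    return [simulate_cohort(s, causal_index=causal_index) for s in specs]


@dataclass(frozen=True)
class LdscSimSpec:
    """Generative model for LD-score regression summary statistics.

    chi2_j = z_j^2 with z_j ~ N(0, 1 + N*h2*l_j/M), or, with a
    per-annotation coefficient vector tau, variance
    1 + N * sum_c tau_c * l_{jc} where l_{jc} are annotation-specific LD
    scores (default a_{jc} * l_j).
    """

    M: int
    ld_scores: np.ndarray
    N: int
    h2: float = 0.0
    annotations: Optional[np.ndarray] = None  # M x C binary
    tau: Optional[np.ndarray] = None  # length C
    annot_ld_scores: Optional[np.ndarray] = None  # M x C
    seed: int = 0

    def __post_init__(self):
        l = np.asarray(self.ld_scores, dtype=float)
        if l.shape != (self.M,):
            raise ValueError("ld_scores must have length M")
        if np.any(l < 1):
            raise ValueError("LD scores must be >= 1")
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("h2 must lie in [0, 1)")
        if (self.tau is None) != (self.annotations is None and self.annot_ld_scores is None):
            if self.tau is not None:
                raise ValueError("tau requires annotations or annot_ld_scores")

    def expected_chi2(self) -> np.ndarray:
        l = np.asarray(self.ld_scores, dtype=float)
        if self.tau is not None:
            if self.annot_ld_scores is not None:
                la = np.asarray(self.annot_ld_scores, dtype=float)
            else:
                la = np.asarray(self.annotations, dtype=float) * l[:, None]
            var = 1.0 + self.N * la @ np.asarray(self.tau, dtype=float)
        else:
            var = 1.0 + self.N * self.h2 * l / self.M
        if np.any(var <= 0):
            raise ValueError("annotation model implies non-positive chi-square variance")
        return var


def simulate_ldsc_sumstats(spec: LdscSimSpec, noiseless: bool = False) -> np.ndarray:
    """Per-SNP chi-square statistics under the LD-score regression model.

    In noiseless mode the expectation itself is returned (useful for exact
    recovery tests of the regression).
    """
    var = spec.expected_chi2()
    if noiseless:
        return var
    rng = np.random.default_rng([spec.seed, 4242])
    z = rng.standard_normal(spec.M) * np.sqrt(var)
    return z**2


def simulate_ldsc_inputs(
    M: int, n_annotations: int = 0, seed: int = 0, mean_ld: float = 50.0,
    annot_frac: float = 0.1,
) -> tuple:
    """Convenience generator of LD scores and a binary annotation matrix.

    Returns (ld_scores, annotations) where ld_scores = 1 + Gamma-distributed
    bulk (mean ``mean_ld``) and annotations is M x (1 + n_annotations) with
    a leading all-SNPs base column and random ``annot_frac`` columns.
    """
    rng = np.random.default_rng([seed, 7171])
    ld = 1.0 + rng.gamma(shape=2.0, scale=(mean_ld - 1.0) / 2.0, size=M)
    cols = [np.ones(M)]
    for _ in range(n_annotations):
        cols.append((rng.random(M) < annot_frac).astype(float))
    return ld, np.column_stack(cols)


def write_cohort_tsv(cohort: CohortData, outdir) -> dict:
    """Write dosages, exposure and phenotype as plain TSV files."""
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = cohort.genotypes.shape[1]
    snp_ids = [f"snp{j + 1:06d}" for j in range(m)]
    paths = {
        "dosages": outdir / "dosages.tsv",
        "exposure": outdir / "exposure.tsv",
        "phenotype": outdir / "phenotype.tsv",
    }
    pd.DataFrame(cohort.genotypes, columns=snp_ids).to_csv(
        paths["dosages"], sep="\t", index=False
    )
    pd.DataFrame({"exposure": cohort.exposure}).to_csv(
        paths["exposure"], sep="\t", index=False
    )
    pd.DataFrame({"phenotype": cohort.phenotype}).to_csv(
        paths["phenotype"], sep="\t", index=False
    )
    return {k: str(v) for k, v in paths.items()}
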