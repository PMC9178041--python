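import numpy as np
import pytest

from gxemeta import CohortSpec, PhenoModel, simulate_cohort


@pytest.fixture(scope="session")
def interaction_cohort():
    """A mid-size cohort with a real interaction at SNP 0 (binary E)."""
    spec = CohortSpec(
        n=4000,
        m=50,
        maf=0.3,
        exposure_kind="binary",
        exposure_param=0.5,
        model=PhenoModel(beta0=0.1, betaG=0.3, betaE=0.4, betaGE=0.2, sigma2=1.0),
        seed=20240917,
    )
    return simulate_cohort(spec, causal_index=0)


@pytest.fixture(scope="session")
def null_sumstats():
    """Summary table from a cohort where no SNP affects the phenotype."""
    from gxemeta import run_gwis

    spec = CohortSpec(
        n=1500,
        m=400,
        maf=(0.1, 0.5),
        exposure_kind="binary",
        exposure_param=0.4,
        model=PhenoModel(betaE=0.3, sigma2=1.0),
        seed=8,
    )
    cohort = simulate_cohort(spec, causal_index=None)
    return cohort, run_gwis(cohort)


def exact_binomial_band(n, p, level=0.99):
    from scipy import stats

    lo, hi = stats.binom.interval(level, n, p)
    return lo / n, hi / n
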