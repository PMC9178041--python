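"""Interaction/marginal model fits, the 1df and 2df tests, stratum
derivation, and the genome-scan wrapper.

statsmodels OLS serves as the independent single-SNP oracle for the
closed-form normal-equation fits."""

import numpy as np
import pytest
from scipy import stats

from gxemeta import (
    CohortSpec,
    DegenerateDesignError,
    PhenoModel,
    fit_interaction_model,
    fit_marginal_model,
    joint_2df_stat,
    run_gwis,
    simulate_cohort,
    stratify_effects,
)
from gxemeta.gwis import InteractionFit, batched_interaction_fit

from conftest import exact_binomial_band


def _gey(seed=0, n=2000, betaG=0.3, betaGE=0.2, betaE=0.4, sigma=1.0, p=0.5):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.3, n).astype(float)
    e = rng.binomial(1, p, n).astype(float)
    y = betaG * g + betaE * e + betaGE * g * e + sigma * rng.standard_normal(n)
    return g, e, y


class TestInteractionFit:
    def test_noiseless_exact_recovery(self):
        g, e, _ = _gey(seed=1)
        y = 0.0 + 0.5 * g + 1.0 * e + 0.25 * g * e
        fit = fit_interaction_model(g, e, y)
        assert fit.betaG_hat == pytest.approx(0.5, abs=1e-10)
        assert fit.betaE_hat == pytest.approx(1.0, abs=1e-10)
        assert fit.betaGE_hat == pytest.approx(0.25, abs=1e-10)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        g, e, y = _gey(seed=2)
        X = sm.add_constant(np.column_stack([g, e, g * e]))
        ref = sm.OLS(y, X).fit()
        fit = fit_interaction_model(g, e, y)
        assert fit.betaG_hat == pytest.approx(ref.params[1], rel=1e-10)
        assert fit.betaGE_hat == pytest.approx(ref.params[3], rel=1e-10)
        assert fit.seGE == pytest.approx(ref.bse[3], rel=1e-10)
        assert fit.cov[0, 1] == pytest.approx(
            ref.cov_params()[1, 3], rel=1e-10
        )
        # the 1df p is the Wald chi-square form of statsmodels' t-ratio
        assert fit.p_1df == pytest.approx(
            stats.chi2.sf(ref.tvalues[3] ** 2, df=1), rel=1e-9
        )

    def test_robust_matches_statsmodels_hc0(self):
        sm = pytest.importorskip("statsmodels.api")
        g, e, y = _gey(seed=3)
        X = sm.add_constant(np.column_stack([g, e, g * e]))
        ref = sm.OLS(y, X).fit(cov_type="HC0")
        fit = fit_interaction_model(g, e, y, robust=True)
        assert fit.seGE == pytest.approx(ref.bse[3], rel=1e-8)

    def test_stratum_slopes_exact(self):
        # binary E, no covariates: betaG equals the E=0 subsample OLS
        # slope; betaG + betaGE equals the E=1 subsample slope, exactly
        g, e, y = _gey(seed=4)
        fit = fit_interaction_model(g, e, y)
        for mask, expect in ((e == 0, fit.betaG_hat),
                             (e == 1, fit.betaG_hat + fit.betaGE_hat)):
            slope = np.polyfit(g[mask], y[mask], 1)[0]
            assert slope == pytest.approx(expect, rel=1e-9)

    def test_all_exposed_degenerate(self):
        g, _, y = _gey(seed=5)
        with pytest.raises(DegenerateDesignError):
            fit_interaction_model(g, np.ones_like(g), y)

    def test_monomorphic_degenerate(self):
        _, e, y = _gey(seed=6)
        with pytest.raises(DegenerateDesignError):
            fit_interaction_model(np.zeros_like(e), e, y)


class TestMarginalFit:
    def test_noiseless_no_interaction_exact(self):
        g, e, _ = _gey(seed=7)
        y = 0.3 * g + 0.4 * e
        fit = fit_marginal_model(g, e, y)
        assert fit.betaM_hat == pytest.approx(0.3, abs=1e-10)

    def test_unbiased_without_interaction(self):
        reps, est = 200, []
        for s in range(reps):
            g, e, y = _gey(seed=1000 + s, n=500, betaGE=0.0)
            est.append(fit_marginal_model(g, e, y).betaM_hat)
        est = np.array(est)
        mc_se = est.std(ddof=1) / np.sqrt(reps)
        assert abs(est.mean() - 0.3) < 2 * mc_se

    def test_marginal_absorbs_prevalence_weighted_interaction(self):
        # with E ~ Bernoulli(p) independent of G: betaM ~= betaG + p*betaGE
        p, reps, est = 0.4, 150, []
        for s in range(reps):
            g, e, y = _gey(seed=2000 + s, n=2000, betaG=0.2, betaGE=0.5, p=p)
            est.append(fit_marginal_model(g, e, y).betaM_hat)
        est = np.array(est)
        mc_se = est.std(ddof=1) / np.sqrt(reps)
        assert abs(est.mean() - (0.2 + p * 0.5)) < 3 * mc_se


class TestJoint2df:
    def test_zero_vector(self):
        chi2, p = joint_2df_stat([0.0, 0.0], np.eye(2))
        assert chi2 == 0.0 and p == 1.0

    def test_diagonal_sums_squared_z(self):
        chi2, _ = joint_2df_stat([0.2, 0.3], np.diag([0.04, 0.01]))
        assert chi2 == pytest.approx((0.2 / 0.2) ** 2 + (0.3 / 0.1) ** 2)

    def test_correlated_case_explicit_inverse(self):
        V = np.array([[0.01, 0.002], [0.002, 0.02]])
        b = np.array([0.3, 0.1])
        chi2, p = joint_2df_stat(b, V)
        Vinv = np.linalg.inv(V)
        assert chi2 == pytest.approx(float(b @ Vinv @ b), rel=1e-12)
        assert chi2 == pytest.approx(9.08, abs=0.01)

    def test_singular_covariance_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            joint_2df_stat([1.0, 1.0], np.ones((2, 2)))


class TestStratify:
    def test_arithmetic_example(self):
        fit = InteractionFit(
            betaG_hat=0.2, betaE_hat=0.0, betaGE_hat=0.1,
            cov=np.array([[0.01, -0.005], [-0.005, 0.02]]),
            n=100, p_1df=0.5, chi2_2df=1.0, p_2df=0.6,
        )
        st = stratify_effects(fit)
        assert st.beta_exposed == pytest.approx(0.3)
        assert st.se_exposed == pytest.approx(np.sqrt(0.02), rel=1e-12)

    def test_null_interaction_strata_identical(self):
        fit = InteractionFit(0.2, 0.0, 0.0, np.diag([0.01, 0.02]), 100, 1, 0, 1)
        st = stratify_effects(fit)
        assert st.beta_unexposed == st.beta_exposed

    def test_point_estimates_match_direct_stratum_ols(self):
        g, e, y = _gey(seed=8)
        st = stratify_effects(fit_interaction_model(g, e, y))
        for mask, (b, _) in ((e == 0, (st.beta_unexposed, None)),
                             (e == 1, (st.beta_exposed, None))):
            slope = np.polyfit(g[mask], y[mask], 1)[0]
            assert slope == pytest.approx(b, rel=1e-9)

    def test_negative_implied_variance_rejected(self):
        fit = InteractionFit(0.1, 0.0, 0.1,
                             np.array([[0.01, -0.5], [-0.5, 0.02]]),
                             100, 1, 0, 1)
        with pytest.raises(ValueError):
            stratify_effects(fit)


class TestRunGwis:
    def test_monomorphic_snp_flagged_and_absent(self, interaction_cohort):
        cohort = interaction_cohort
        g = cohort.genotypes.copy()
        g[:, 3] = 0.0
        from gxemeta import CohortData

        modified = CohortData(genotypes=g, exposure=cohort.exposure,
                              phenotype=cohort.phenotype, truth=cohort.truth)
        tab = run_gwis(modified)
        assert len(tab) == g.shape[1] - 1
        assert len(tab.attrs["excluded"]) == 1
        assert "snp000004" not in set(tab["SNPID"])

    def test_record_count_bound(self, interaction_cohort):
        tab = run_gwis(interaction_cohort)
        m = interaction_cohort.genotypes.shape[1]
        assert len(tab) + len(tab.attrs["excluded"]) == m

    def test_null_scan_pvalues_uniform(self, null_sumstats):
        _, tab = null_sumstats
        assert stats.kstest(tab["P_1DF"], "uniform").pvalue > 0.01

    def test_causal_snp_detected(self, interaction_cohort):
        tab = run_gwis(interaction_cohort)
        assert tab.iloc[0]["P_2DF"] < 1e-10


class TestAlleleFlip:
    def test_flip_equivariance(self, interaction_cohort):
        """Recoding G -> 2-G flips coefficient signs and leaves every test
        statistic unchanged to >= 12 significant digits."""
        cohort = interaction_cohort
        g = cohort.genotypes[:, 0]
        e, y = cohort.exposure, cohort.phenotype
        a = fit_interaction_model(g, e, y)
        b = fit_interaction_model(2.0 - g, e, y)
        assert b.betaG_hat == pytest.approx(-a.betaG_hat, rel=1e-12)
        assert b.betaGE_hat == pytest.approx(-a.betaGE_hat, rel=1e-12)
        assert b.chi2_2df == pytest.approx(a.chi2_2df, rel=1e-12)
        assert b.p_1df == pytest.approx(a.p_1df, rel=1e-12)
        ma = fit_marginal_model(g, e, y)
        mb = fit_marginal_model(2.0 - g, e, y)
        assert mb.betaM_hat == pytest.approx(-ma.betaM_hat, rel=1e-12)
        assert mb.p_marg == pytest.approx(ma.p_marg, rel=1e-12)


def test_type_one_error_in_exact_binomial_band():
    """1df test at alpha=0.05 under the null across 10,000 SNPs stays in
    the exact binomial 99% acceptance band."""
    spec = CohortSpec(n=600, m=10_000, maf=(0.1, 0.5), exposure_param=0.5,
                      model=PhenoModel(betaE=0.2), seed=314)
    cohort = simulate_cohort(spec, causal_index=None)
    fit = batched_interaction_fit(cohort.genotypes, cohort.exposure,
                                  cohort.phenotype)
    ok = fit["ok"]
    z = fit["betaGE"][ok] / np.sqrt(fit["varGE"][ok])
    p = stats.chi2.sf(z**2, df=1)
    rate = np.mean(p < 0.05)
    lo, hi = exact_binomial_band(ok.sum(), 0.05)
    assert lo <= rate <= hi
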