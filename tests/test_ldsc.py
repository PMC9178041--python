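"""LD-score regression fits, jackknife behaviour, partitioned enrichment,
stratum difference tests and the heterogeneity-filter sensitivity curve."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxemeta import (
    LdscSimSpec,
    enrichment_comparison,
    h2_difference_test,
    het_filter_sensitivity,
    ldsc_fit,
    ldsc_partitioned,
    simulate_ldsc_inputs,
    simulate_ldsc_sumstats,
)


def _ld(M, seed=1):
    ld, _ = simulate_ldsc_inputs(M, seed=seed)
    return ld


class TestPlainFit:
    def test_noiseless_exact_recovery(self):
        ld = _ld(3000)
        chi2 = simulate_ldsc_sumstats(
            LdscSimSpec(M=3000, ld_scores=ld, N=40_000, h2=0.3), noiseless=True
        )
        fit = ldsc_fit(chi2, ld, N=40_000, n_blocks=100)
        assert fit.h2 == pytest.approx(0.3, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)

    def test_constant_ld_scores_unidentifiable(self):
        with pytest.raises(ValueError):
            ldsc_fit(np.ones(500), np.full(500, 25.0), N=1000, n_blocks=50)

    def test_jackknife_se_positive_under_noise(self):
        ld = _ld(2000, seed=2)
        chi2 = simulate_ldsc_sumstats(
            LdscSimSpec(M=2000, ld_scores=ld, N=30_000, h2=0.2, seed=3)
        )
        fit = ldsc_fit(chi2, ld, N=30_000, n_blocks=100)
        assert fit.h2_se > 0 and fit.intercept_se > 0

    def test_jackknife_se_scales_with_m(self):
        # SE should shrink roughly like 1/sqrt(M)
        ses = []
        for M in (5000, 20_000):
            ld = _ld(M, seed=4)
            reps = []
            for s in range(8):
                chi2 = simulate_ldsc_sumstats(
                    LdscSimSpec(M=M, ld_scores=ld, N=30_000, h2=0.25,
                                seed=100 + s)
                )
                reps.append(ldsc_fit(chi2, ld, N=30_000, n_blocks=100).h2_se)
            ses.append(np.mean(reps))
        ratio = ses[0] / ses[1]
        assert abs(ratio - 2.0) < 0.5  # within 25% of sqrt(4)


class TestPartitioned:
    def test_single_base_annotation_reduces_to_plain(self):
        ld = _ld(3000, seed=5)
        annot = np.ones((3000, 1))
        chi2 = simulate_ldsc_sumstats(
            LdscSimSpec(M=3000, ld_scores=ld, N=40_000, h2=0.3), noiseless=True
        )
        fit = ldsc_partitioned(chi2, annot * ld[:, None], annot,
                               N=40_000, n_blocks=100)
        assert fit.h2 == pytest.approx(0.3, abs=1e-8)
        assert fit.enrichment[0] == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_annotations_recover_tau_ratio(self):
        # signal concentrated in one half: enrichment ratio matches tau ratio
        M = 4000
        ld = np.full(M, 30.0) + np.arange(M) % 7  # non-constant scores
        half = np.zeros(M); half[: M // 2] = 1
        annot = np.column_stack([np.ones(M), half])
        tau = np.array([1e-5, 4e-5])
        spec = LdscSimSpec(M=M, ld_scores=ld, N=20_000, tau=tau,
                           annotations=annot)
        chi2 = simulate_ldsc_sumstats(spec, noiseless=True)
        fit = ldsc_partitioned(chi2, annot * ld[:, None], annot, N=20_000,
                               n_blocks=100, annot_names=["base", "half"])
        assert np.allclose(fit.tau, tau, rtol=1e-6)
        # per-SNP h2 is 5e-5 inside, 1e-5 outside: half holds 5/6 of h2
        assert fit.enrichment[1] == pytest.approx((5 / 6) / 0.5, rel=1e-6)

    def test_empty_annotation_rejected(self):
        M = 500
        annot = np.column_stack([np.ones(M), np.zeros(M)])
        ld = _ld(M, seed=6)
        with pytest.raises(ValueError):
            ldsc_partitioned(np.ones(M), annot * ld[:, None], annot, N=1000,
                             n_blocks=50)

    def test_disjoint_partition_sums_to_total(self):
        M = 2000
        ld = _ld(M, seed=7)
        half = np.zeros(M); half[: M // 2] = 1
        annot = np.column_stack([np.ones(M), half, 1 - half])
        chi2 = simulate_ldsc_sumstats(
            LdscSimSpec(M=M, ld_scores=ld, N=30_000, h2=0.2), noiseless=True
        )
        fit = ldsc_partitioned(chi2, annot * ld[:, None], annot, N=30_000,
                               n_blocks=100)
        assert fit.h2_c[1] + fit.h2_c[2] == pytest.approx(fit.h2, rel=1e-8)

    def test_bonferroni_reported(self):
        M = 1000
        ld = _ld(M, seed=8)
        rng = np.random.default_rng(9)
        annot = np.column_stack(
            [np.ones(M)] + [(rng.random(M) < 0.3).astype(float) for _ in range(3)]
        )
        chi2 = simulate_ldsc_sumstats(
            LdscSimSpec(M=M, ld_scores=ld, N=30_000, h2=0.2, seed=10)
        )
        fit = ldsc_partitioned(chi2, annot * ld[:, None], annot, N=30_000,
                               n_blocks=50)
        assert fit.bonferroni == pytest.approx(0.05 / 3)


class TestDifference:
    def test_equal_h2_null(self):
        z, p = h2_difference_test(0.2, 0.05, 0.2, 0.05)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_arithmetic_example(self):
        z, p = h2_difference_test(0.15, 0.03, 0.11, 0.03)
        assert z == pytest.approx(0.943, abs=0.001)
        assert p == pytest.approx(0.346, abs=0.002)

    def test_back_derived_stratum_comparison(self):
        # SEs recovered from Wald p-values of h2=0.19 (p=7.0e-17) and
        # h2=0.13 (p=3.1e-10); their difference test lands near 0.052
        se_a = 0.19 / stats.norm.isf(7.0e-17 / 2)
        se_b = 0.13 / stats.norm.isf(3.1e-10 / 2)
        _, p = h2_difference_test(0.19, se_a, 0.13, se_b)
        assert 0.050 <= p <= 0.054


@pytest.fixture(scope="module")
def homogeneous():
    M = 4000
    ld = _ld(M, seed=11)
    chi2 = simulate_ldsc_sumstats(
        LdscSimSpec(M=M, ld_scores=ld, N=30_000, h2=0.25, seed=12)
    )
    p_het = np.random.default_rng(13).uniform(size=M)
    return chi2, ld, p_het


class TestHetFilter:
    def test_zero_threshold_keeps_all(self, homogeneous):
        chi2, ld, p_het = homogeneous
        tab = het_filter_sensitivity(chi2, ld, p_het, N=30_000,
                                     thresholds=(0.0,), n_blocks=100)
        assert tab.iloc[0]["M_kept"] == len(chi2)
        plain = ldsc_fit(chi2, ld, N=30_000, n_blocks=100)
        assert tab.iloc[0]["h2"] == pytest.approx(plain.h2, rel=1e-12)

    def test_kept_counts_monotone(self, homogeneous):
        chi2, ld, p_het = homogeneous
        tab = het_filter_sensitivity(chi2, ld, p_het, N=30_000,
                                     thresholds=(0.0, 0.01, 0.05, 0.2),
                                     n_blocks=100)
        assert (np.diff(tab["M_kept"]) <= 0).all()
        assert tab["selected"].sum() == 1

    def test_homogeneous_curve_flat(self, homogeneous):
        chi2, ld, p_het = homogeneous
        tab = het_filter_sensitivity(chi2, ld, p_het, N=30_000,
                                     thresholds=(0.0, 0.05, 0.2),
                                     n_blocks=100)
        base = tab.iloc[0]
        for _, row in tab.iterrows():
            assert abs(row["h2"] - base["h2"]) < 3 * np.hypot(
                row["h2_se"], base["h2_se"]
            )

    def test_all_filtered_rejected(self, homogeneous):
        chi2, ld, _ = homogeneous
        with pytest.raises(ValueError):
            het_filter_sensitivity(chi2, ld, np.zeros(len(chi2)) + 1e-9,
                                   N=30_000, thresholds=(0.5,))


class TestComparison:
    def _fit(self, boost=None, seed=14):
        M = 3000
        ld = _ld(M, seed=seed)
        rng = np.random.default_rng(seed + 1)
        annot = np.column_stack(
            [np.ones(M)] + [(rng.random(M) < 0.2).astype(float) for _ in range(4)]
        )
        names = ["base", "a1", "a2", "a3", "a4"]
        tau = np.full(5, 2e-6)
        if boost:
            tau[names.index(boost)] *= 30
        chi2 = simulate_ldsc_sumstats(
            LdscSimSpec(M=M, ld_scores=ld, N=30_000, tau=tau,
                        annotations=annot),
            noiseless=True,
        )
        return ldsc_partitioned(chi2, annot * ld[:, None], annot, N=30_000,
                                n_blocks=100, annot_names=names)

    def test_identical_fits_zero_delta_corr_one(self):
        fit = self._fit()
        comp = enrichment_comparison(fit, fit, grouping={
            "a1": "g1", "a2": "g1", "a3": "g2", "a4": "g2"})
        assert all(d == pytest.approx(0.0, abs=1e-12)
                   for d in comp.delta_enrichment.values())
        assert comp.enrichment_corr == pytest.approx(1.0)

    def test_boosted_group_has_extreme_delta(self):
        unexp = self._fit(boost="a3")
        exp = self._fit()
        comp = enrichment_comparison(unexp, exp, grouping={
            "a1": "g1", "a2": "g1", "a3": "g2", "a4": "g3"})
        assert max(comp.delta_enrichment,
                   key=lambda g: comp.delta_enrichment[g]) == "g2"

    def test_no_shared_annotations_rejected(self):
        fit = self._fit()
        other = self._fit()
        other.annot_names = ["base2", "x1", "x2", "x3", "x4"]
        with pytest.raises(ValueError):
            enrichment_comparison(fit, other, grouping={})


def test_stochastic_recovery_within_jackknife_ses():
    """h2=0.25 at M=20,000, N=50,000 recovered within 2 jackknife SEs in
    at least 93 of 100 stochastic replicates."""
    M, N, h2 = 20_000, 50_000, 0.25
    ld = _ld(M, seed=15)
    hits = 0
    for s in range(100):
        chi2 = simulate_ldsc_sumstats(
            LdscSimSpec(M=M, ld_scores=ld, N=N, h2=h2, seed=1000 + s)
        )
        fit = ldsc_fit(chi2, ld, N=N, n_blocks=200)
        hits += abs(fit.h2 - h2) < 2 * fit.h2_se
    assert hits >= 93
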