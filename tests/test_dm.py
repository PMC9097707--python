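"""Differential-methylation core: filters, normalisation, dispersion, tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tgmeth
from tgmeth.dm import (DMPSet, betabinom_wald_test, call_dmps,
                       call_methylated_sites, estimate_dispersion,
                       filter_min_coverage, filter_variability,
                       logistic_regression_test, normalize_median_coverage,
                       qc_samples, shrink_dispersion)
from tgmeth.stats_util import adjust_bh

from conftest import make_matrix


class TestQC:
    def test_uniform_samples_unflagged(self):
        m = make_matrix(np.zeros((50, 4)), np.full((50, 4), 10))
        rep = qc_samples(m)
        assert not rep["flag_low_coverage"].any()
        assert not rep["flag_meth_outlier"].any()

    def test_zero_coverage_sample_flagged(self):
        total = np.full((50, 3), 10)
        total[:, 1] = 0
        rep = qc_samples(make_matrix(np.zeros((50, 3)), total))
        assert rep["flag_low_coverage"].tolist() == [False, True, False]

    def test_doubled_methylation_sample_flagged_by_percentile(self):
        rng = np.random.default_rng(0)
        n, s = 4000, 10
        total = np.full((n, s), 10)
        p = np.full((n, s), 0.2)
        p[:, 3] = 0.4  # doubled methylation probability
        meth = rng.binomial(total, p)
        rep = qc_samples(make_matrix(meth, total))
        # independent percentile oracle by sorting
        pct = 100 * (meth * 2 >= total).sum(axis=0) / n
        others = np.sort(np.delete(pct, 3))
        assert pct[3] > others[-1]
        assert rep["flag_meth_outlier"].iloc[3]


class TestCallRule:
    def test_extremes(self):
        m0 = make_matrix(np.zeros((20, 2)), np.full((20, 2), 5))
        assert call_methylated_sites(m0).tolist() == [0.0, 0.0]
        m1 = make_matrix(np.full((20, 2), 5), np.full((20, 2), 5))
        assert call_methylated_sites(m1).tolist() == [100.0, 100.0]

    def test_half_fraction_inclusive_and_zero_total_excluded(self):
        meth = np.array([[1], [1], [0]])
        total = np.array([[2], [3], [0]])  # 0.5 called; 0.33 not; uncovered not
        m = make_matrix(meth, total)
        assert call_methylated_sites(m)[0] == pytest.approx(100 / 3)


class TestFilters:
    def test_min_coverage_boundary(self):
        m = make_matrix(np.zeros((3, 2)), np.full((3, 2), 5))
        assert filter_min_coverage(m, m.samples, 5).n_sites == 3
        total = np.full((3, 2), 5)
        total[1, 0] = 4
        m2 = make_matrix(np.zeros((3, 2)), total)
        kept = filter_min_coverage(m2, m2.samples, 5)
        assert kept.site_keys() == [("chr1", 10), ("chr1", 30)]

    def test_min_coverage_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        total = rng.integers(0, 12, (20, 5))
        m = make_matrix(np.zeros((20, 5)), total)
        kept = filter_min_coverage(m, m.samples, 5)
        oracle = [i for i in range(20) if all(total[i, j] >= 5 for j in range(5))]
        assert kept.sites["pos"].tolist() == [(i + 1) * 10 for i in oracle]

    def test_sd_filter_boundary_inclusive(self):
        # two samples at 49% and 50%: SD = 0.7071 >= 0.5 kept;
        # identical percentages: SD = 0 removed
        meth = np.array([[49, 50], [50, 50]])
        total = np.full((2, 2), 100)
        m = make_matrix(meth, total)
        kept = filter_variability(m, m.samples, sd_min=0.5)
        assert kept.site_keys() == [("chr1", 10)]
        # exact boundary: values 0 and x giving SD exactly 0.5
        meth2 = np.array([[0, 1]])
        total2 = np.array([[100, 141]])  # 0% and 1/141 = 0.70922% -> SD 0.5015
        m2 = make_matrix(meth2, total2)
        assert filter_variability(m2, m2.samples, 0.5).n_sites == 1

    def test_sd_filter_matches_two_pass_oracle(self):
        rng = np.random.default_rng(2)
        total = rng.integers(5, 30, (30, 6))
        meth = rng.binomial(total, 0.3)
        m = make_matrix(meth, total)
        kept = set(filter_variability(m, m.samples, 0.5).sites["pos"])
        for i in range(30):
            pct = 100 * meth[i] / total[i]
            mean = sum(pct) / len(pct)
            sd = (sum((x - mean) ** 2 for x in pct) / (len(pct) - 1)) ** 0.5
            assert (((i + 1) * 10) in kept) == (sd >= 0.5)


class TestNormalization:
    def test_identity_when_medians_equal(self):
        m = make_matrix(np.ones((9, 3)), np.full((9, 3), 8))
        out = normalize_median_coverage(m)
        np.testing.assert_array_equal(out.total, m.total)
        np.testing.assert_array_equal(out.meth, m.meth)

    def test_two_sample_hand_computation(self):
        # medians 4 and 8 -> reference 6 -> factors 1.5 and 0.75
        total = np.array([[4, 8]] * 5)
        meth = np.zeros((5, 2), dtype=int)
        out = normalize_median_coverage(make_matrix(meth, total))
        assert out.total[0, 0] == 6  # 4 * 1.5
        assert out.total[0, 1] == 6  # 8 * 0.75

    def test_rounding_half_up_and_cap(self):
        # methylated 3, total 4, factor 1.5 -> meth 4.5 rounds to 5, total 6
        total = np.array([[4, 8], [4, 8], [4, 8]])
        meth = np.array([[3, 0], [4, 0], [0, 0]])
        out = normalize_median_coverage(make_matrix(meth, total))
        assert out.meth[0, 0] == 5 and out.total[0, 0] == 6
        assert out.meth[1, 0] == 6  # cap respected: 6 <= total 6
        assert out.meth[1, 0] <= out.total[1, 0]

    def test_all_zero_sample_raises(self):
        total = np.array([[5, 0], [5, 0]])
        with pytest.raises(ValueError, match="all-zero"):
            normalize_median_coverage(make_matrix(np.zeros((2, 2)), total))

    def test_zero_totals_stay_zero(self):
        total = np.array([[4, 8], [0, 8], [4, 8]])
        out = normalize_median_coverage(make_matrix(np.zeros((3, 2)), total))
        assert out.total[1, 0] == 0


class TestDispersion:
    def test_binomial_data_clamps_low_and_shrinks_to_prior(self):
        rng = np.random.default_rng(3)
        n = np.maximum(rng.poisson(20, (2000, 6)), 1)
        k = rng.binomial(n, 0.4)
        raw, dof, info = estimate_dispersion(k, n, np.arange(3), np.arange(3, 6))
        assert np.median(raw) == pytest.approx(1e-6)
        star = shrink_dispersion(raw, dof, informative=info)
        # phi* pulled toward the (near-clamp) prior for every site
        assert np.median(star) < 1e-3

    def test_identical_raw_phi_is_fixed_point(self):
        raw = np.full(200, 0.07)
        dof = np.full(200, 10.0)
        for d0 in (1.0, 20.0, 500.0):
            star = shrink_dispersion(raw, dof, d0=d0)
            np.testing.assert_allclose(star, 0.07, rtol=1e-12)

    def test_parameter_recovery_simulation(self):
        """5000 sites at phi = 0.1, 6 samples, coverage 20: mean shrunk
        dispersion lands within [0.05, 0.2]."""
        rng = np.random.default_rng(0)
        N, S, phi = 5000, 6, 0.1
        p = rng.uniform(0.2, 0.8, N)
        a = p * (1 - phi) / phi
        b = (1 - p) * (1 - phi) / phi
        pc = rng.beta(a[:, None] * np.ones(S), b[:, None] * np.ones(S))
        n = np.maximum(rng.poisson(20, (N, S)), 1)
        k = rng.binomial(n, pc)
        raw, dof, info = estimate_dispersion(k, n, np.arange(3), np.arange(3, 6))
        star = shrink_dispersion(raw, dof, informative=info)
        assert 0.05 <= star.mean() <= 0.2

    def test_few_sites_fall_back_to_fixed_prior(self):
        with pytest.warns(UserWarning, match="prior"):
            star = shrink_dispersion(np.full(5, 0.5), np.full(5, 10.0))
        assert (star < 0.5).all()  # pulled toward log(0.01)


class TestWald:
    def test_identical_groups_null_identity(self):
        meth = np.tile(np.array([[3]]), (1, 6))
        total = np.tile(np.array([[10]]), (1, 6))
        m = make_matrix(meth, total)
        res = betabinom_wald_test(m, m.samples[:3], m.samples[3:], 0.05)
        assert res["meth_diff"].iloc[0] == 0
        assert res["p_value"].iloc[0] == 1.0

    def test_phi_zero_equals_two_proportion_z(self):
        """At phi* = 0 the statistic equals the two-proportion z on pooled
        counts: case 30/100 vs control 10/100, closed form."""
        m = make_matrix([[30, 10]], [[100, 100]])
        res = betabinom_wald_test(m, [m.samples[0]], [m.samples[1]], 0.0)
        p1, p0 = 0.30, 0.10
        z_expected = (p1 - p0) / np.sqrt(p1 * (1 - p1) / 100 + p0 * (1 - p0) / 100)
        assert res["z"].iloc[0] == pytest.approx(z_expected, abs=1e-10)
        assert res["p_value"].iloc[0] == pytest.approx(
            2 * stats.norm.sf(z_expected), abs=1e-10)

    def test_degenerate_variance_gives_p_one(self):
        m = make_matrix([[0, 0]], [[10, 10]])
        res = betabinom_wald_test(m, [m.samples[0]], [m.samples[1]], 0.0)
        assert res["z"].iloc[0] == 0 and res["p_value"].iloc[0] == 1.0

    def test_zero_group_coverage_site_skipped(self):
        m = make_matrix([[0, 3]], [[0, 10]])
        res = betabinom_wald_test(m, [m.samples[0]], [m.samples[1]], 0.0)
        assert len(res) == 0 and res.attrs["n_skipped"] == 1

    def test_power_on_planted_effect(self):
        """A 40-point planted gain at coverage 10, 3 vs 9, is detected at
        p < 0.01 in >= 90% of replicate sites."""
        rng = np.random.default_rng(3)
        M, Sn, phi = 2000, 12, 0.02
        planted = np.zeros(M, bool)
        planted[:300] = True
        n = np.maximum(rng.poisson(10, (M, Sn)), 1)
        pmat = np.full((M, Sn), 0.002)
        pmat[planted, :3] = 0.402
        a = pmat * (1 - phi) / phi
        b = (1 - pmat) * (1 - phi) / phi
        k = rng.binomial(n, rng.beta(a, b))
        m = make_matrix(k, n)
        res = tgmeth.test_generation(m, m.samples[:3], m.samples[3:])
        pv = res["p_value"].to_numpy()[planted]
        assert (pv < 0.01).mean() >= 0.90


class TestLogistic:
    def test_identical_groups(self):
        m = make_matrix([[3, 3]], [[10, 10]])
        res = logistic_regression_test(m, [m.samples[0]], [m.samples[1]])
        assert res["lrt"].iloc[0] == 0 and res["p_value"].iloc[0] == 1.0

    def test_lrt_matches_direct_two_binomial_likelihood(self):
        m = make_matrix([[30, 10]], [[100, 100]])
        res = logistic_regression_test(m, [m.samples[0]], [m.samples[1]])

        def ll(k, n, p):
            return k * np.log(p) + (n - k) * np.log(1 - p)

        lrt = 2 * (ll(30, 100, 0.3) + ll(10, 100, 0.1)
                   - ll(30, 100, 0.2) - ll(10, 100, 0.2))
        assert res["lrt"].iloc[0] == pytest.approx(lrt, abs=1e-10)
        assert res["p_value"].iloc[0] == pytest.approx(
            stats.chi2.sf(lrt, 1), abs=1e-6)

    def test_agrees_with_statsmodels_glm(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        for _ in range(5):
            k1, n1 = int(rng.integers(1, 20)), 25
            k0, n0 = int(rng.integers(1, 20)), 25
            m = make_matrix([[k1, k0]], [[n1, n0]])
            res = logistic_regression_test(m, [m.samples[0]], [m.samples[1]])
            endog = np.array([[k1, n1 - k1], [k0, n0 - k0]])
            exog = sm.add_constant(np.array([1.0, 0.0]))
            full = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, np.ones((2, 1)),
                          family=sm.families.Binomial()).fit()
            lrt_sm = 2 * (full.llf - null.llf)
            assert res["lrt"].iloc[0] == pytest.approx(lrt_sm, abs=1e-6)

    def test_rank_concordance_with_wald(self):
        """Logistic and Wald p-values agree in rank (rho >= 0.9) on simulated
        data, mirroring a confirmation analysis."""
        rng = np.random.default_rng(5)
        M, Sn = 800, 12
        p = rng.uniform(0.05, 0.95, M)
        effect = np.where(rng.random(M) < 0.3, rng.uniform(-0.3, 0.3, M), 0.0)
        n = np.maximum(rng.poisson(12, (M, Sn)), 1)
        pmat = np.tile(p[:, None], (1, Sn))
        pmat[:, :3] = np.clip(pmat[:, :3] + effect[:, None], 0, 1)
        k = rng.binomial(n, pmat)
        m = make_matrix(k, n)
        rw = tgmeth.test_generation(m, m.samples[:3], m.samples[3:],
                                    method="wald")
        rl = tgmeth.test_generation(m, m.samples[:3], m.samples[3:],
                                    method="logistic")
        rho = stats.spearmanr(rw["p_value"], rl["p_value"]).statistic
        assert rho >= 0.9


class TestBH:
    def test_hand_case(self):
        q = adjust_bh(np.array([0.01, 0.02, 0.03]))
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert adjust_bh(np.array([0.42]))[0] == pytest.approx(0.42)

    def test_matches_reference_implementation(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(6)
        p = rng.random(1000)
        q = adjust_bh(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_ref, atol=1e-12)

    def test_empty_and_invalid(self):
        assert adjust_bh(np.array([])).size == 0
        with pytest.raises(ValueError):
            adjust_bh(np.array([1.2]))


def test_call_dmps_directions():
    res = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [1, 2, 3],
                        "meth_diff": [20.0, -15.0, 10.0],
                        "q_value": [0.01, 0.02, 0.50]})
    dmps = call_dmps(res, fdr=0.05)
    assert dmps.sites == {("chr1", 1): "hyper", ("chr1", 2): "hypo"}


def test_filter_chain_idempotent(small_experiment):
    _, matrix, sheet, _ = small_experiment
    design = tgmeth.ComparisonDesign.from_samplesheet(sheet, "microcystin")
    prepared = tgmeth.prepare_comparison(matrix, design)
    again = tgmeth.prepare_comparison(prepared, design)
    # the surviving site set is stable; re-normalising integer counts can
    # shift individual cells by at most one read of rounding
    assert again.site_keys() == prepared.site_keys()
    rel = np.abs(again.total - prepared.total) / np.maximum(prepared.total, 1)
    assert rel.max() <= 0.15
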