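"""MAX3 statistic, null correlations and trivariate-normal p-values."""

import numpy as np
import pytest
from scipy import stats

from npodds.effects import GroupedSample
from npodds.association import z_test
from npodds.max3 import NullCorrelation, max3_pvalue, max3_test, null_correlations


class TestRectangleProbability:
    @pytest.mark.parametrize("m", [1.0, 2.0, 2.5])
    def test_independent_limit_closed_form(self, m):
        p = max3_pvalue(m, np.eye(3))
        expected = 1.0 - (2 * stats.norm.cdf(m) - 1.0) ** 3
        assert p == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize("m", [1.5, 2.2])
    def test_perfectly_correlated_limit(self, m):
        corr = np.ones((3, 3))
        p = max3_pvalue(m, corr)
        assert p == pytest.approx(2 * stats.norm.sf(m), abs=1e-4)

    def test_deterministic_across_calls(self):
        corr = NullCorrelation(0.6, 0.5, 0.2)
        vals = {max3_pvalue(2.0, corr) for _ in range(5)}
        assert len(vals) == 1

    def test_bracketed_by_single_test_and_bonferroni(self, null_sample):
        res = max3_test(null_sample)
        zs = [z_test(null_sample, m).p_value
              for m in ("recessive", "additive", "dominant")]
        assert res.p_value >= min(zs) - 1e-4
        assert res.p_value <= min(1.0, sum(zs)) + 1e-4

    def test_agrees_with_parametric_bootstrap(self, null_sample):
        corr = null_correlations(null_sample)
        m = 1.8
        p = max3_pvalue(m, corr)
        rng = np.random.default_rng(31)
        w = rng.multivariate_normal(np.zeros(3), corr.matrix, size=100_000,
                                    method="eigh")
        p_mc = np.mean(np.abs(w).max(axis=1) >= m)
        se = np.sqrt(p_mc * (1 - p_mc) / 100_000)
        assert abs(p - p_mc) < 3 * se + 1e-3


class TestNullCorrelations:
    def test_psd_and_in_range(self, null_sample):
        corr = null_correlations(null_sample)
        w = np.linalg.eigvalsh(corr.matrix)
        assert w.min() > -1e-10
        for g in (corr.gamma_RA, corr.gamma_AD, corr.gamma_RD):
            assert -1.0 <= g <= 1.0

    def test_monte_carlo_oracle(self):
        # estimated gammas vs empirical correlations of (Z_R, Z_A, Z_D)
        # across exchangeable replicates at the MAF 0.30 design
        rng = np.random.default_rng(32)
        n0, n1, n2 = 735, 630, 135
        zs, gams = [], []
        for _ in range(1200):
            s = GroupedSample(rng.gumbel(size=n0), rng.gumbel(size=n1),
                              rng.gumbel(size=n2))
            zs.append([z_test(s, m).statistic
                       for m in ("recessive", "additive", "dominant")])
            c = null_correlations(s)
            gams.append([c.gamma_RA, c.gamma_AD, c.gamma_RD])
        zs = np.asarray(zs)
        emp = np.corrcoef(zs.T)
        emp_vec = np.array([emp[0, 1], emp[1, 2], emp[0, 2]])
        est_vec = np.asarray(gams).mean(axis=0)
        for e, g in zip(emp_vec, est_vec):
            se = (1 - e ** 2) / np.sqrt(zs.shape[0])
            assert abs(e - g) < 3 * se + 0.02

    def test_shared_rare_group_noise_dominates_gamma_ra(self):
        # with a small genotype-2 group, both Z_R and the f12 part of Z_A
        # are driven by the same few genotype-2 placements, so gamma_RA
        # is large; the MC-oracle test above checks the estimates globally
        rng = np.random.default_rng(33)
        vals = [null_correlations(
            GroupedSample(rng.gumbel(size=400), rng.gumbel(size=400),
                          rng.gumbel(size=30))).gamma_RA
                for _ in range(40)]
        assert np.mean(vals) > 0.85

    def test_recessive_dominant_share_least_information(self):
        # Z_R and Z_D overlap only through the pooled middles, so gamma_RD
        # is the smallest of the three correlations in a balanced design
        rng = np.random.default_rng(34)
        s = GroupedSample(rng.gumbel(size=300), rng.gumbel(size=300),
                          rng.gumbel(size=300))
        corr = null_correlations(s)
        assert corr.gamma_RD < corr.gamma_RA
        assert corr.gamma_RD < corr.gamma_AD
        assert corr.gamma_RD > 0.0

    def test_tied_duplicate_group_handled(self):
        # y2 an exact copy of y1: massive cross-group ties must not break
        # the correlation estimates
        rng = np.random.default_rng(38)
        y0, y1 = rng.gumbel(size=200), rng.gumbel(size=200)
        corr = null_correlations(GroupedSample(y0, y1, y1.copy()))
        assert np.all(np.isfinite(corr.matrix))
        assert np.linalg.eigvalsh(corr.matrix).min() > -1e-10


class TestMax3Test:
    def test_statistic_is_max_abs_component(self, null_sample):
        res = max3_test(null_sample)
        zs = [z_test(null_sample, m).statistic
              for m in ("recessive", "additive", "dominant")]
        assert res.statistic == pytest.approx(max(abs(z) for z in zs), abs=1e-12)

    def test_permutation_method_close_to_asymptotic(self):
        rng = np.random.default_rng(35)
        s = GroupedSample(rng.gumbel(size=60), 0.4 + rng.gumbel(size=50),
                          0.8 + rng.gumbel(size=30))
        asym = max3_test(s, method="mvn")
        perm = max3_test(s, method="permutation", n_perm=4000, seed=36)
        se = np.sqrt(max(perm.p_value, 1e-4) * (1 - perm.p_value) / 4000)
        assert abs(asym.p_value - perm.p_value) < 3 * se + 0.03

    def test_signed_option_less_conservative_for_positive_trend(self, rng):
        s = GroupedSample(rng.gumbel(size=200), 0.3 + rng.gumbel(size=150),
                          0.6 + rng.gumbel(size=60))
        two = max3_test(s, signed=False)
        one = max3_test(s, signed=True)
        assert one.p_value <= two.p_value + 1e-6
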