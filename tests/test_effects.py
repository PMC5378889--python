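"""Placement estimators against brute-force O(n^2) oracles and invariants."""

import numpy as np
import pytest
from scipy.stats import rankdata

from npodds.effects import (EstimationError, GroupedSample,
                            covariance_shared_cmp, covariance_shared_ref,
                            effect_influence, estimate_f, influence_cov,
                            model_effect, variance_f)
from npodds.error_models import TGEVParams, true_risk_for_shift

from conftest import (brute_cov_shared_cmp, brute_cov_shared_ref, brute_f,
                      brute_variance, random_small_groups)


class TestEstimateF:
    def test_printed_examples(self):
        assert estimate_f([1, 3], [2, 4]).f_hat == 0.75
        assert estimate_f([1, 2], [2, 3]).f_hat == 0.875  # one tie at 2

    def test_identical_multiset_gives_half(self):
        x = [3.0, 1.0, 3.0, 7.0]
        assert estimate_f(x, x).f_hat == 0.5

    def test_matches_brute_force_on_small_tie_rich_samples(self, rng):
        for ref, cmp in random_small_groups(rng):
            got = estimate_f(ref, cmp).f_hat
            assert got == pytest.approx(brute_f(ref, cmp), abs=1e-12)

    def test_complement_symmetry_exact(self, rng):
        for ref, cmp in random_small_groups(rng, n_sets=30):
            assert estimate_f(ref, cmp).f_hat + estimate_f(cmp, ref).f_hat == 1.0

    def test_equals_normalized_mann_whitney_u(self, rng):
        for _ in range(20):
            ref = rng.choice([0.0, 1.0, 2.0, 5.0], rng.integers(2, 8))
            cmp = rng.choice([0.0, 1.0, 2.0, 5.0], rng.integers(2, 8))
            ranks = rankdata(np.concatenate([ref, cmp]))
            u = ranks[len(ref):].sum() - len(cmp) * (len(cmp) + 1) / 2
            assert estimate_f(ref, cmp).f_hat == pytest.approx(
                u / (len(ref) * len(cmp)), abs=1e-12)

    def test_empty_group_raises(self):
        with pytest.raises(EstimationError):
            estimate_f([], [1.0])
        with pytest.raises(EstimationError):
            estimate_f([1.0], [])

    def test_lambda_at_one_is_inf_with_warning(self):
        est = estimate_f([1.0, 2.0], [3.0, 4.0])
        assert est.f_hat == 1.0
        with pytest.warns(RuntimeWarning):
            assert est.lambda_hat == np.inf


class TestVariance:
    def test_all_ties_gives_zero(self):
        assert variance_f([2.0, 2.0, 2.0], [2.0, 2.0]) == 0.0

    def test_matches_brute_force(self, rng):
        for ref, cmp in random_small_groups(rng):
            if len(ref) < 2 or len(cmp) < 2:
                continue
            assert variance_f(ref, cmp) == pytest.approx(
                brute_variance(ref, cmp), abs=1e-12)

    def test_degenerate_sizes_raise(self):
        with pytest.raises(EstimationError):
            variance_f([1.0], [2.0, 3.0])

    def test_nonnegative(self, rng):
        for ref, cmp in random_small_groups(rng, n_sets=30):
            if len(ref) >= 2 and len(cmp) >= 2:
                assert variance_f(ref, cmp) >= 0

    def test_monte_carlo_variance_oracle(self):
        # the placement variance estimate must track the sampling variance
        # of f_hat across null replicates within 10%
        rng = np.random.default_rng(11)
        n = 1000
        fs, vs = [], []
        for _ in range(5000):
            a, b = rng.gumbel(size=n), rng.gumbel(size=n)
            est = estimate_f(a, b)
            fs.append(est.f_hat)
            vs.append(est.var_f)
        emp = np.var(fs, ddof=1)
        assert np.mean(vs) == pytest.approx(emp, rel=0.10)


class TestCovariances:
    def test_identical_comparison_groups(self, rng):
        ref = rng.normal(size=6)
        cmp = rng.normal(size=4)
        got = covariance_shared_ref(ref, cmp, cmp).cov
        from conftest import brute_placements
        pa, _ = brute_placements(ref, cmp)
        assert got == pytest.approx(np.var(pa, ddof=1) / len(ref), abs=1e-12)

    def test_shared_ref_matches_brute_force(self, rng):
        for _ in range(25):
            ref = rng.choice([0.0, 1.0, 2.0, 4.0], rng.integers(2, 6))
            a = rng.choice([0.0, 1.0, 2.0, 4.0], rng.integers(1, 6))
            b = rng.choice([0.0, 1.0, 2.0, 4.0], rng.integers(1, 6))
            assert covariance_shared_ref(ref, a, b).cov == pytest.approx(
                brute_cov_shared_ref(ref, a, b), abs=1e-12)

    def test_shared_cmp_matches_brute_force(self, rng):
        for _ in range(25):
            ra = rng.choice([0.0, 1.0, 3.0, 4.0], rng.integers(1, 6))
            sh = rng.choice([0.0, 1.0, 3.0, 4.0], rng.integers(2, 6))
            rb = rng.choice([0.0, 1.0, 3.0, 4.0], rng.integers(1, 6))
            assert covariance_shared_cmp(ra, sh, rb).cov == pytest.approx(
                brute_cov_shared_cmp(ra, sh, rb), abs=1e-12)

    def test_shared_constant_vector_gives_zero(self):
        assert covariance_shared_cmp([1.0, 2.0], [5.0, 5.0, 5.0], [7.0, 8.0]).cov == 0.0

    def test_cauchy_schwarz(self, rng):
        for _ in range(20):
            ref = rng.normal(size=8)
            a, b = rng.normal(size=5), rng.normal(size=6)
            c = abs(covariance_shared_ref(ref, a, b).cov)
            bound = np.sqrt(variance_f(ref, a) * variance_f(ref, b))
            assert c <= bound + 1e-12

    def test_shared_ref_monte_carlo_oracle(self):
        # correlation implied by the estimator vs the empirical correlation
        # of (f1_hat, f2_hat) across exchangeable replicates
        rng = np.random.default_rng(13)
        n0, n1, n2 = 500, 400, 200
        f1s, f2s, rhos = [], [], []
        for _ in range(2000):
            y0, y1, y2 = rng.gumbel(size=n0), rng.gumbel(size=n1), rng.gumbel(size=n2)
            e1, e2 = estimate_f(y0, y1), estimate_f(y0, y2)
            f1s.append(e1.f_hat)
            f2s.append(e2.f_hat)
            c = covariance_shared_ref(y0, y1, y2).cov
            rhos.append(c / np.sqrt(e1.var_f * e2.var_f))
        emp = np.corrcoef(f1s, f2s)[0, 1]
        se = (1 - emp ** 2) / np.sqrt(len(f1s))
        assert abs(np.mean(rhos) - emp) < 3 * se + 0.02

    def test_shared_cmp_monte_carlo_oracle(self):
        rng = np.random.default_rng(14)
        n0, n1, n2 = 500, 400, 200
        f1s, f12s, rhos = [], [], []
        for _ in range(2000):
            y0, y1, y2 = rng.gumbel(size=n0), rng.gumbel(size=n1), rng.gumbel(size=n2)
            e1, e12 = estimate_f(y0, y1), estimate_f(y1, y2)
            f1s.append(e1.f_hat)
            f12s.append(e12.f_hat)
            c = covariance_shared_cmp(y0, y1, y2).cov
            rhos.append(c / np.sqrt(e1.var_f * e12.var_f))
        emp = np.corrcoef(f1s, f12s)[0, 1]
        se = (1 - emp ** 2) / np.sqrt(len(f1s))
        assert emp < 0  # opposite roles of the shared group anti-correlate
        assert abs(np.mean(rhos) - emp) < 3 * se + 0.02


class TestModelEffect:
    def test_exchangeable_identical_groups_give_half(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        s = GroupedSample(x, x.copy(), x.copy())
        for model in ("recessive", "additive", "dominant"):
            assert model_effect(s, model).f_hat == 0.5

    def test_recessive_pools_reference(self):
        s = GroupedSample([1.0, 4.0], [2.0, 5.0], [3.0, 6.0])
        got = model_effect(s, "recessive").f_hat
        assert got == pytest.approx(brute_f([1, 4, 2, 5], [3, 6]), abs=1e-12)

    def test_dominant_pools_comparison(self):
        s = GroupedSample([1.0, 4.0], [2.0, 5.0], [3.0, 6.0])
        got = model_effect(s, "dominant").f_hat
        assert got == pytest.approx(brute_f([1, 4], [2, 5, 3, 6]), abs=1e-12)

    def test_additive_is_weighted_combination(self):
        s = GroupedSample([1.0, 4.0, 0.0], [2.0, 5.0], [3.0, 6.0])
        n0, n1, n2 = 3, 2, 2
        w1 = (n0 + n1) / (n0 + 2 * n1 + n2)
        w12 = (n1 + n2) / (n0 + 2 * n1 + n2)
        expected = w1 * brute_f(s.y0, s.y1) + w12 * brute_f(s.y1, s.y2)
        assert model_effect(s, "additive").f_hat == pytest.approx(expected, abs=1e-12)

    def test_empty_group_model_undefined(self):
        s = GroupedSample([1.0, 2.0], [3.0, 4.0], [])
        with pytest.raises(EstimationError):
            model_effect(s, "recessive")
        with pytest.raises(EstimationError):
            model_effect(s, "additive")
        assert model_effect(s, "dominant").f_hat == 1.0  # pooled {1,2} nonempty

    def test_additive_unbiased_under_null(self):
        rng = np.random.default_rng(15)
        fs = [model_effect(GroupedSample(rng.gumbel(size=200), rng.gumbel(size=150),
                                         rng.gumbel(size=60)), "additive").f_hat
              for _ in range(2000)]
        se = np.std(fs, ddof=1) / np.sqrt(len(fs))
        assert abs(np.mean(fs) - 0.5) < 3 * se

    def test_consistency_at_large_n(self):
        rng = np.random.default_rng(16)
        params = TGEVParams()
        d = 0.4
        f_true = true_risk_for_shift(d, params)
        misses = 0
        for _ in range(40):
            a = params.sample(2000, rng)
            b = d + params.sample(2000, rng)
            if abs(estimate_f(a, b).f_hat - f_true) >= 0.02:
                misses += 1
        assert misses <= 4  # ~95% of replicates within 0.02


class TestInfluence:
    def test_influence_variance_matches_placement_variance(self, null_sample):
        # Gram-matrix variance of an unpooled effect equals the placement
        # estimator up to the per-subgroup ddof correction (O(1/n))
        for model in ("recessive", "additive", "dominant"):
            infl = effect_influence(null_sample, model)
            v_gram = influence_cov(infl, infl)
            v_direct = model_effect(null_sample, model).var_f
            assert v_gram == pytest.approx(v_direct, rel=0.02)

    def test_influence_fhat_matches_model_effect(self, tiny_sample):
        for model in ("recessive", "additive", "dominant"):
            assert effect_influence(tiny_sample, model).f_hat == pytest.approx(
                model_effect(tiny_sample, model).f_hat, abs=1e-12)
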