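import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from meanet import (
    MixtureSpec,
    estimate_epsilon,
    estimate_marginal_density,
    estimate_null_sigma,
    generate_z_mixture,
    local_fdr_statistics,
    run_fdr,
    select_significant,
)


class TestNullSigma:
    def test_recovers_scale_two(self):
        est = [
            estimate_null_sigma(np.random.default_rng(s).normal(0, 2, 10_000))
            for s in range(20)
        ]
        assert 1.9 < np.mean(est) < 2.1
        assert all(1.8 < e < 2.2 for e in est)

    def test_standard_normal_within_five_percent(self):
        est = [
            estimate_null_sigma(np.random.default_rng(s).normal(0, 1, 10_000))
            for s in range(20)
        ]
        assert abs(np.mean(est) - 1.0) < 0.05

    def test_robust_to_five_percent_contamination(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 1, 10_000)
        clean = estimate_null_sigma(z)
        z[: len(z) // 20] = 50.0
        assert abs(estimate_null_sigma(z) - clean) / clean < 0.10

    def test_quantile_methods_also_consistent(self):
        z = np.random.default_rng(1).normal(0, 2, 50_000)
        for method in ("central-mad", "mad"):
            assert estimate_null_sigma(z, method=method) == pytest.approx(2.0, rel=0.05)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_null_sigma(np.zeros(1000))
        with pytest.raises(ValueError, match="100"):
            estimate_null_sigma(np.random.default_rng(0).normal(size=50))


class TestEpsilon:
    def test_pure_null_near_zero(self):
        est = [
            estimate_epsilon(np.random.default_rng(s).normal(0, 1, 3481), sigma=1.0)
            for s in range(20)
        ]
        assert np.mean(est) < 0.02

    def test_recovers_five_percent_mixture(self):
        est = []
        for s in range(30):
            rm, _ = generate_z_mixture(MixtureSpec(epsilon=0.05, seed=s))
            sigma = estimate_null_sigma(rm.z)
            est.append(estimate_epsilon(rm.z, sigma))
        assert 0.03 < np.mean(est) < 0.07

    def test_half_mixture_strong_separation(self):
        rm, _ = generate_z_mixture(MixtureSpec(epsilon=0.5, f1_loc=8.0, seed=2))
        assert estimate_epsilon(rm.z, sigma=estimate_null_sigma(rm.z)) >= 0.4

    def test_clipped_to_valid_range(self):
        z = np.random.default_rng(0).normal(10, 1, 1000)  # everything non-null
        assert 0.0 <= estimate_epsilon(z, sigma=1.0) <= 1.0 - 1e-6


class TestMarginalDensity:
    def test_kde_close_to_standard_normal(self):
        grid = np.linspace(-3, 3, 121)
        sup = []
        for seed in range(10):
            f = estimate_marginal_density(np.random.default_rng(seed).normal(size=10_000))
            sup.append(np.max(np.abs(f(grid) - stats.norm.pdf(grid))))
        assert np.mean(sup) < 0.02

    def test_unimodal_shape(self):
        z = np.random.default_rng(1).normal(size=5000)
        f = estimate_marginal_density(z)
        assert f(np.median(z)) > f(z.max())

    def test_integrates_to_one(self):
        z = np.random.default_rng(2).normal(size=5000)
        f = estimate_marginal_density(z)
        grid = np.linspace(z.min() - 5, z.max() + 5, 4001)
        assert np.trapezoid(f(grid), grid) == pytest.approx(1.0, abs=1e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            estimate_marginal_density(np.ones(1000))


class TestLocalFdrStatistics:
    def test_null_model_equals_marginal_gives_t_one(self):
        z = np.random.default_rng(0).normal(size=(59, 59))
        f0 = lambda x: stats.norm.pdf(x)
        t = local_fdr_statistics(z, epsilon=0.0, sigma=1.0, f_hat=f0)
        np.testing.assert_allclose(t, 1.0)

    def test_far_outlier_gets_small_t(self):
        rm, _ = generate_z_mixture(MixtureSpec(epsilon=0.05, seed=3))
        res = run_fdr(rm)
        extreme = np.abs(rm.z) > 8 * res.sigma_hat
        assert (res.t[extreme] < 0.05).all()

    def test_t_strictly_decreasing_in_epsilon(self):
        z = np.random.default_rng(4).normal(size=(30, 30))
        f = estimate_marginal_density(z)
        t1 = local_fdr_statistics(z, 0.2, 1.0, f)
        t2 = local_fdr_statistics(z, 0.4, 1.0, f)
        inner = t1 < 1.0
        assert (t2[inner] < t1[inner]).all()

    def test_untested_entries_get_t_one(self):
        z = np.random.default_rng(5).normal(size=(59, 59))
        mask = np.ones_like(z, bool)
        np.fill_diagonal(mask, False)
        f = estimate_marginal_density(z, tested_mask=mask)
        t = local_fdr_statistics(z, 0.1, 1.0, f, tested_mask=mask)
        np.testing.assert_allclose(np.diagonal(t), 1.0)


def prefix_scan_oracle(values, level):
    """Independent selection rule: check every prefix of the sorted
    statistics explicitly and keep the longest with mean <= level."""
    v = np.sort(np.asarray(values))
    best, running = 0, 0.0
    for i, x in enumerate(v, start=1):
        running += x
        if running / i <= level:
            best = i
    return best


class TestSelectSignificant:
    def test_worked_example(self):
        t = np.array([0.01, 0.02, 0.10, 0.30])
        k, mask = select_significant(t, level=0.05)
        assert k == 3  # prefix means 0.010, 0.015, 0.0433, 0.1075
        assert mask.tolist() == [True, True, True, False]

    def test_all_ones_selects_nothing(self):
        k, mask = select_significant(np.ones((10, 10)), level=0.05)
        assert k == 0 and not mask.any()

    def test_single_statistic_below_level(self):
        k, mask = select_significant(np.array([0.04]), level=0.05)
        assert k == 1 and mask.all()

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_prefix_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 500))
        t = np.clip(rng.beta(0.3, 1.0, size=n), 0, 1)
        level = float(rng.uniform(0.01, 0.3))
        k, mask = select_significant(t, level=level)
        assert k == prefix_scan_oracle(t, level)
        assert mask.sum() == k

    def test_discoveries_nested_in_level(self):
        rng = np.random.default_rng(6)
        t = rng.uniform(0, 1, size=(40, 40))
        _, m1 = select_significant(t, level=0.02)
        _, m2 = select_significant(t, level=0.10)
        assert (m1 <= m2).all()  # subset

    def test_deterministic_tie_breaking(self):
        t = np.full(6, 0.03)
        k, mask = select_significant(t, level=0.05)
        assert k == 6 and mask.all()
        t2 = np.array([0.03, 0.03, 0.2, 0.2])
        k2, mask2 = select_significant(t2, level=0.05)
        assert k2 == 2 and mask2.tolist() == [True, True, False, False]


class TestRunFdr:
    def test_pure_null_yields_no_or_few_discoveries(self):
        fdp = []
        for s in range(10):
            rm, truth = generate_z_mixture(MixtureSpec(epsilon=0.0, seed=s))
            res = run_fdr(rm)
            # V/max(R, 1) convention: 0 when nothing is rejected
            fdp.append(res.n_discoveries / max(res.n_discoveries, 1) if res.n_discoveries else 0.0)
        assert np.mean(fdp) <= 0.2

    def test_power_at_strong_separation(self):
        powers = []
        for s in range(10):
            rm, truth = generate_z_mixture(MixtureSpec(seed=s))
            res = run_fdr(rm)
            powers.append((res.significant_mask & truth).sum() / truth.sum())
        assert np.mean(powers) > 0.5

    def test_permutation_equivariance(self):
        rm, _ = generate_z_mixture(MixtureSpec(seed=9))
        res = run_fdr(rm.z)
        rng = np.random.default_rng(0)
        perm = rng.permutation(rm.z.size)
        z_perm = rm.z.ravel()[perm].reshape(rm.z.shape)
        res_perm = run_fdr(z_perm)
        np.testing.assert_allclose(res_perm.t.ravel(), res.t.ravel()[perm], atol=1e-12)

    def test_diagonal_masked_out_of_ranking(self):
        rm, _ = generate_z_mixture(MixtureSpec(seed=10))
        rm.diagonal_policy = "zero"
        res = run_fdr(rm)
        assert res.n_tests == 59 * 58
        assert not np.diagonal(res.significant_mask).any()

    def test_result_serializable(self):
        rm, _ = generate_z_mixture(MixtureSpec(seed=11))
        res = run_fdr(rm)
        header = res.to_json()
        assert "epsilon_hat" in header and "sigma_method" in header
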