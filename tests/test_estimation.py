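import math

import numpy as np
import pytest
from scipy import stats

from quantmct.contrasts import QuantileSpec
from quantmct.estimation import (
    EstimationError,
    GroupedSample,
    bandwidth_rule,
    cov_bootstrap,
    cov_interval,
    cov_kernel,
    density_at_quantile_kernel,
    empirical_quantile,
    estimate_covariance,
    pooled_quantile_vector,
)

M1 = QuantileSpec((0.5,))
M3 = QuantileSpec((0.25, 0.5, 0.75))


class TestEmpiricalQuantile:
    @pytest.mark.parametrize("sample,p,expected", [
        ([3, 1, 2], 0.5, 2),      # ceil(1.5) = 2nd order statistic
        ([1, 2, 3, 4], 0.5, 2),   # ceil(2) = 2
        ([1, 2, 3, 4], 0.75, 3),
        ([5], 0.9, 5),
    ])
    def test_left_continuous_inverse(self, sample, p, expected):
        assert empirical_quantile(sample, p) == expected

    def test_matches_numpy_inverted_cdf(self, rng):
        x = rng.standard_normal(37)
        for p in (0.1, 0.25, 0.5, 0.9):
            assert empirical_quantile(x, p) == np.quantile(x, p, method="inverted_cdf")

    def test_errors(self):
        with pytest.raises(ValueError):
            empirical_quantile([], 0.5)
        with pytest.raises(ValueError):
            empirical_quantile([1.0], 1.0)


class TestPooledQuantileVector:
    def test_two_group_medians(self):
        gs = GroupedSample([[1, 2, 3], [4, 5, 6]])
        assert np.allclose(pooled_quantile_vector(gs, M1).values, [2, 5])

    def test_within_group_monotone_in_p(self, rng):
        gs = GroupedSample([rng.standard_normal(25) for _ in range(3)])
        q = pooled_quantile_vector(gs, M3).by_group(3)
        assert np.all(np.diff(q, axis=1) >= 0)

    def test_invariant_to_within_group_permutation(self, rng):
        x = rng.standard_normal(20)
        a = pooled_quantile_vector(GroupedSample([x, x + 1]), M3).values
        b = pooled_quantile_vector(
            GroupedSample([rng.permutation(x), rng.permutation(x + 1)]), M3
        ).values
        assert np.array_equal(a, b)


class TestBandwidth:
    def test_rule_of_thumb_value(self):
        # SD = 1, IQR = 1.34 -> 0.9 * 100^(-1/5)
        x = stats.norm.ppf((np.arange(1, 101) - 0.5) / 100)
        x = x / np.std(x, ddof=1)  # exact unit SD
        q25, q75 = np.quantile(x, [0.25, 0.75])
        expected = 0.9 * 100 ** (-0.2) * min(1.0, (q75 - q25) / 1.34)
        assert bandwidth_rule(x) == pytest.approx(expected)

    def test_scale_equivariance(self, rng):
        x = rng.standard_normal(50)
        assert bandwidth_rule(3.0 * x) == pytest.approx(3.0 * bandwidth_rule(x))

    def test_zero_iqr_falls_back_to_sd(self):
        # 30 equal values plus two symmetric outliers: IQR = 0, SD = 2
        a = math.sqrt(62.0)
        x = np.concatenate([np.zeros(30), [a, -a]])
        assert np.std(x, ddof=1) == pytest.approx(2.0)
        assert bandwidth_rule(x) == pytest.approx(0.9 * 32 ** (-0.2) * 2.0)  # = 0.9

    def test_constant_sample_warns_and_uses_unit_scale(self):
        with pytest.warns(RuntimeWarning):
            h = bandwidth_rule(np.full(16, 3.0))
        assert h == pytest.approx(0.9 * 16 ** (-0.2))


class TestKernelDensity:
    def test_single_point_kernel(self):
        assert density_at_quantile_kernel([0.0], 0.0, 1.0) == \
            pytest.approx(stats.norm.pdf(0.0))

    def test_translation_invariance(self, rng):
        x = rng.standard_normal(40)
        v1 = density_at_quantile_kernel(x, 0.3, 0.5)
        v2 = density_at_quantile_kernel(x + 10, 10.3, 0.5)
        assert v1 == pytest.approx(v2)

    def test_recovers_normal_density_at_zero(self, rng):
        x = rng.standard_normal(20000)
        f = density_at_quantile_kernel(x, 0.0, bandwidth_rule(x))
        assert f == pytest.approx(1.0 / math.sqrt(2 * math.pi), rel=0.05)


class TestCovKernel:
    def test_single_group_normal_median_block(self, rng):
        gs = GroupedSample([rng.standard_normal(20000)])
        block = cov_kernel(gs, M1).blocks[0]
        assert block[0, 0] == pytest.approx(math.pi / 2, rel=0.05)

    def test_kappa_prefactor_doubles_block(self, rng):
        x = rng.standard_normal(200)
        single = cov_kernel(GroupedSample([x]), M1).blocks[0]
        halved = cov_kernel(GroupedSample([x, rng.standard_normal(200)]), M1).blocks[0]
        assert halved[0, 0] == pytest.approx(2.0 * single[0, 0])

    def test_off_diagonal_positive_for_quartiles(self, rng):
        gs = GroupedSample([rng.standard_normal(500)])
        block = cov_kernel(gs, QuantileSpec((0.25, 0.75))).blocks[0]
        assert block[0, 1] > 0
        assert block[0, 1] == pytest.approx(block[1, 0])


class TestCovBootstrap:
    def test_constant_sample_raises(self):
        gs = GroupedSample([np.full(20, 7.0)])
        with pytest.raises(EstimationError):
            cov_bootstrap(gs, M1, n_boot=100, seed=0)

    def test_normal_median_block(self, rng):
        gs = GroupedSample([rng.standard_normal(20000)])
        block = cov_bootstrap(gs, M1, n_boot=2000, seed=5).blocks[0]
        assert block[0, 0] == pytest.approx(math.pi / 2, rel=0.25)

    def test_deterministic_given_seed(self, rng):
        gs = GroupedSample([rng.standard_normal(60), rng.standard_normal(40)])
        a = cov_bootstrap(gs, M3, n_boot=200, seed=42)
        b = cov_bootstrap(gs, M3, n_boot=200, seed=42)
        for ba, bb in zip(a.blocks, b.blocks):
            assert np.array_equal(ba, bb)


class TestCovInterval:
    def test_normal_grid_reciprocal_density(self):
        # deterministic sample: standard normal inverse CDF on a 1..99 grid
        grid = stats.norm.ppf(np.arange(1, 100) / 100)
        ce = cov_interval(GroupedSample([grid]), M1)
        inv_f = 1.0 / ce.density_values[0, 0]
        assert inv_f == pytest.approx(math.sqrt(2 * math.pi), rel=0.15)

    def test_scale_equivariance(self, rng):
        x = rng.standard_normal(300)
        b1 = cov_interval(GroupedSample([x]), M1).blocks[0][0, 0]
        b2 = cov_interval(GroupedSample([3.0 * x]), M1).blocks[0][0, 0]
        assert b2 == pytest.approx(9.0 * b1)

    def test_tied_values_raise(self):
        with pytest.raises(EstimationError):
            cov_interval(GroupedSample([np.full(5, 1.0)]), M1)

    def test_tiny_sample_raises(self):
        # a single observation cannot bracket the quantile (L = U)
        with pytest.raises(EstimationError):
            cov_interval(GroupedSample([[1.0]]), M1)


DISTS = {
    "normal": stats.norm(),
    "lognormal": stats.lognorm(1.0),
    "t3": stats.t(3),
}


def closed_form_block(dist, probs):
    q = dist.ppf(probs)
    f = dist.pdf(q)
    pa, pb = np.meshgrid(probs, probs, indexing="ij")
    return (np.minimum(pa, pb) - pa * pb) / np.outer(f, f)


@pytest.mark.parametrize("dist_name", list(DISTS))
def test_all_estimators_recover_asymptotic_covariance(dist_name):
    """Parameter recovery: each estimator's average over independent large
    samples matches the closed-form covariance of the quartile vector within
    10% on the diagonal."""
    dist = DISTS[dist_name]
    probs = np.array(M3.probabilities)
    target = closed_form_block(dist, probs)
    n, reps = 20000, 6
    acc = {"kernel": [], "bootstrap": [], "interval": []}
    rng = np.random.default_rng(99)
    for rep in range(reps):
        gs = GroupedSample([dist.rvs(size=n, random_state=rng)])
        acc["kernel"].append(cov_kernel(gs, M3).blocks[0])
        acc["bootstrap"].append(
            cov_bootstrap(gs, M3, n_boot=800, seed=rep).blocks[0])
        acc["interval"].append(cov_interval(gs, M3).blocks[0])
    for method, blocks in acc.items():
        mean_block = np.mean(blocks, axis=0)
        rel = np.abs(np.diag(mean_block) - np.diag(target)) / np.diag(target)
        assert np.all(rel < 0.10), (method, dist_name, rel)


class TestCovarianceProperties:
    @pytest.mark.parametrize("method", ["kernel", "bootstrap", "interval"])
    def test_blocks_symmetric_psd(self, rng, method):
        gs = GroupedSample([rng.standard_normal(80), rng.standard_normal(120)])
        kwargs = {"seed": 0, "n_boot": 300} if method == "bootstrap" else {}
        ce = estimate_covariance(gs, M3, method, **kwargs)
        for b in ce.blocks:
            assert np.allclose(b, b.T)
            assert np.min(np.linalg.eigvalsh(b)) > -1e-8

    @pytest.mark.parametrize("method", ["kernel", "bootstrap", "interval"])
    def test_location_shift_invariance_and_scale_law(self, rng, method):
        x = [rng.standard_normal(70), rng.standard_normal(90)]
        kwargs = {"seed": 3, "n_boot": 300} if method == "bootstrap" else {}
        base = estimate_covariance(GroupedSample(x), M3, method, **kwargs)
        shifted = estimate_covariance(
            GroupedSample([g + 5.0 for g in x]), M3, method, **kwargs)
        scaled = estimate_covariance(
            GroupedSample([2.0 * g for g in x]), M3, method, **kwargs)
        for b0, bs, bc in zip(base.blocks, shifted.blocks, scaled.blocks):
            assert np.allclose(b0, bs, rtol=1e-10, atol=1e-10)
            assert np.allclose(4.0 * b0, bc, rtol=1e-8, atol=1e-10)

    def test_full_matrix_is_block_diagonal(self, rng):
        gs = GroupedSample([rng.standard_normal(50), rng.standard_normal(60)])
        ce = cov_kernel(gs, M3)
        full = ce.full
        assert full.shape == (6, 6)
        assert np.allclose(full[:3, 3:], 0.0)
        assert np.allclose(full[:3, :3], ce.blocks[0])

    def test_unknown_method_rejected(self, rng):
        gs = GroupedSample([rng.standard_normal(30), rng.standard_normal(30)])
        with pytest.raises(ValueError):
            estimate_covariance(gs, M1, "jackknife")
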