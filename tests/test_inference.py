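import numpy as np
import pytest

from quantmct.contrasts import QuantileSpec, make_dunnett, make_tukey
from quantmct.estimation import GroupedSample, pooled_quantile_vector
from quantmct.inference import (
    HypothesisSpec,
    run_equivalence_tost,
    run_multiple_test,
    simultaneous_cis,
)

from conftest import random_grouped_sample

M1 = QuantileSpec((0.5,))


class TestHypothesisSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            HypothesisSpec(alternative="one_sided")
        with pytest.raises(ValueError):
            HypothesisSpec(direction="up")
        with pytest.raises(ValueError):
            HypothesisSpec(alpha=1.5)
        with pytest.raises(ValueError):
            HypothesisSpec(alternative="equivalence")  # missing delta
        with pytest.raises(ValueError):
            HypothesisSpec(alternative="equivalence", delta=-1.0)


class TestRunMultipleTest:
    def test_margins_at_estimates_give_no_rejections(self, rng):
        gs = random_grouped_sample(rng, sizes=(20, 25, 30))
        fam = make_tukey(3)
        eps = fam.matrix @ pooled_quantile_vector(gs, M1).values
        res = run_multiple_test(gs, M1, fam, HypothesisSpec(margins=eps),
                                method="bonf-asymptotic")
        assert np.allclose(res.statistics, 0.0)
        assert not res.reject.any()
        assert not res.reject_global

    def test_global_decision_is_or_of_locals(self, rng):
        for i in range(10):
            gs = random_grouped_sample(rng)
            res = run_multiple_test(gs, M1, make_tukey(gs.k), HypothesisSpec(),
                                    method="mctp-asymptotic", n_mc=5000, seed=i)
            assert res.reject_global == bool(res.reject.any())

    @pytest.mark.parametrize("method,kwargs", [
        ("bonf-asymptotic", {}),
        ("mctp-asymptotic", {"n_mc": 20_000}),
        ("bonf-permutation", {"n_resamples": 399}),
        ("mctp-bootstrap", {"n_resamples": 399}),
    ])
    @pytest.mark.parametrize("alternative", ["two_sided", "noninferiority"])
    def test_rejection_iff_margin_outside_interval(self, rng, method, kwargs,
                                                   alternative):
        """Duality: the same critical value drives decision and bound."""
        for i in range(6):
            gs = random_grouped_sample(rng, dist=["normal", "lognormal"][i % 2])
            fam = make_tukey(gs.k)
            eps = rng.normal(0, 0.5, fam.r)
            res = run_multiple_test(
                gs, M1, fam, HypothesisSpec(alternative, margins=eps),
                method=method, seed=100 + i, **kwargs)
            outside = (eps < res.ci_lower) | (eps > res.ci_upper)
            assert np.array_equal(res.reject, outside)

    @pytest.mark.parametrize("method,kwargs", [
        ("bonf-asymptotic", {}),
        ("bonf-permutation", {"n_resamples": 999}),
        ("mctp-bootstrap", {"n_resamples": 999}),
    ])
    def test_p_below_alpha_iff_rejection(self, rng, method, kwargs):
        # up to the 1/(B+1) resampling granularity at the boundary
        for i in range(6):
            gs = random_grouped_sample(rng)
            fam = make_dunnett(gs.k)
            res = run_multiple_test(gs, M1, fam, HypothesisSpec(),
                                    method=method, seed=i, **kwargs)
            gran = fam.r / (res.n_resamples + 1.0) if res.n_resamples else 0.0
            for p, rej in zip(res.pvalues, res.reject):
                if abs(p - res.alpha) > gran:
                    assert (p <= res.alpha) == rej

    def test_location_shift_leaves_median_contrast_results_unchanged(self, rng):
        x = [rng.standard_normal(20) for _ in range(4)]
        fam = make_tukey(4)
        a = run_multiple_test(GroupedSample(x), M1, fam, HypothesisSpec(),
                              method="bonf-permutation", n_resamples=299, seed=9)
        b = run_multiple_test(GroupedSample([g + 100.0 for g in x]), M1, fam,
                              HypothesisSpec(), method="bonf-permutation",
                              n_resamples=299, seed=9)
        assert np.allclose(a.statistics, b.statistics)
        assert np.array_equal(a.reject, b.reject)

    def test_mctp_rejects_whenever_bonferroni_does(self, rng):
        # power ordering through the critical-value dominance (same covariance)
        hits = 0
        for i in range(15):
            gs = random_grouped_sample(rng)
            fam = make_tukey(gs.k)
            bonf = run_multiple_test(gs, M1, fam, HypothesisSpec(),
                                     method="bonf-asymptotic")
            mctp = run_multiple_test(gs, M1, fam, HypothesisSpec(),
                                     method="mctp-asymptotic", n_mc=50_000, seed=i)
            margin_ok = np.abs(np.abs(mctp.statistics) - mctp.critical_values) > 0.02
            assert np.all(~bonf.reject | mctp.reject | ~margin_ok)
            hits += int(bonf.reject.any())
        assert hits > 0  # the check saw actual rejections

    def test_direction_less_mirrors_bounds(self, rng):
        # many-to-one noninferiority in the "base minus group" direction:
        # H0_l: q_base - q_l >= margin, reported as (-inf, upper] bounds
        gs = random_grouped_sample(rng, sizes=(30,) * 5)
        fam = make_dunnett(5, base=5)
        res = run_multiple_test(
            gs, M1, fam,
            HypothesisSpec("noninferiority", direction="less", margins=7.0),
            method="bonf-asymptotic")
        assert res.estimates == pytest.approx(
            fam.matrix @ pooled_quantile_vector(gs, M1).values)
        assert np.all(np.isneginf(res.ci_lower))
        assert np.all(np.isfinite(res.ci_upper))
        # decision equals the mirrored greater-direction run
        mirrored = run_multiple_test(
            gs, M1, fam.negated(),
            HypothesisSpec("noninferiority", direction="greater", margins=-7.0),
            method="bonf-asymptotic")
        assert np.array_equal(res.reject, mirrored.reject)
        assert res.ci_upper == pytest.approx(-mirrored.ci_lower)

    def test_unknown_method_rejected(self, rng):
        gs = random_grouped_sample(rng)
        with pytest.raises(ValueError):
            run_multiple_test(gs, M1, make_tukey(gs.k), HypothesisSpec(),
                              method="holm")


class TestSimultaneousCis:
    def test_zero_critical_value_degenerates_to_point(self):
        lo, hi = simultaneous_cis([1.5], [2.0], 100, [0.0], "two_sided")
        assert lo[0] == hi[0] == 1.5

    def test_two_sided_width_and_scale_equivariance(self):
        lo, hi = simultaneous_cis([1.0], [3.0], 25, [2.0], "two_sided")
        assert hi[0] - lo[0] == pytest.approx(2 * 3.0 * 2.0 / 5.0)
        lo2, hi2 = simultaneous_cis([3.0], [9.0], 25, [2.0], "two_sided")
        assert lo2[0] == pytest.approx(3 * lo[0])
        assert hi2[0] == pytest.approx(3 * hi[0])

    def test_toy_duality(self):
        # T = 3 vs critical 1.96: the interval excludes 0 iff |T| > 1.96
        est, scale, n = 3.0, np.sqrt(6.0), 6
        lo, hi = simultaneous_cis([est], [scale], n, [1.96], "two_sided")
        assert (0.0 < lo[0]) == (abs(np.sqrt(n) * est / scale) > 1.96)


class TestEquivalenceTost:
    def test_huge_delta_concludes_equivalence(self, rng):
        gs = GroupedSample([rng.standard_normal(60) for _ in range(3)])
        res = run_equivalence_tost(gs, M1, make_tukey(3), delta=1e6,
                                   method="bonf-asymptotic")
        assert res.reject.all() and res.reject_global

    def test_tiny_delta_never_rejects(self, rng):
        gs = GroupedSample([rng.standard_normal(60) for _ in range(3)])
        res = run_equivalence_tost(gs, M1, make_tukey(3), delta=1e-9,
                                   method="bonf-asymptotic")
        assert not res.reject.any()

    def test_sign_flip_symmetry(self, rng):
        x = [rng.standard_normal(40) for _ in range(3)]
        fam = make_tukey(3)
        a = run_equivalence_tost(GroupedSample(x), M1, fam, delta=0.5,
                                 method="bonf-asymptotic")
        b = run_equivalence_tost(GroupedSample([-g for g in x]), M1, fam,
                                 delta=0.5, method="bonf-asymptotic")
        assert np.array_equal(a.reject, b.reject)

    def test_interval_is_intersection_of_one_sided_bounds(self, rng):
        gs = GroupedSample([rng.standard_normal(50) for _ in range(3)])
        res = run_equivalence_tost(gs, M1, make_tukey(3), delta=1.0,
                                   method="bonf-asymptotic")
        assert np.all(res.ci_lower <= res.ci_upper + 1e-12)
        assert np.all(np.isfinite(res.ci_lower) & np.isfinite(res.ci_upper))
        assert res.extra["one_sided_level"] == pytest.approx(0.025)

    def test_requires_positive_delta(self, rng):
        gs = random_grouped_sample(rng)
        with pytest.raises(ValueError):
            run_equivalence_tost(gs, M1, make_tukey(gs.k), delta=0.0,
                                 method="bonf-asymptotic")
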