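import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit.estimators import (
    cochran_q,
    ivw,
    leave_one_out,
    max_likelihood,
    mr_egger,
    wald_ratio,
    weighted_median,
)
from mrkit.harmonize import HarmonizedSet
from mrkit.synthetic_gwas import SimulationConfig, simulate_two_sample

from conftest import make_hset


class TestWaldRatio:
    def test_hand_arithmetic(self):
        est, se = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est == pytest.approx(0.5)
        assert se == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        est, _ = wald_ratio(0.1, 0.01, 0.0, 0.02)
        assert est == 0.0

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)

    def test_negative_beta_x_keeps_se_positive(self):
        _, se = wald_ratio(-0.1, 0.01, 0.05, 0.02)
        assert se == pytest.approx(0.2)

    def test_second_order_se_matches_monte_carlo(self):
        # oracle: SD of the ratio of two independent normals at 1e6 draws
        rng = np.random.default_rng(42)
        ratio = rng.normal(0.05, 0.02, 1_000_000) / rng.normal(0.1, 0.01, 1_000_000)
        mc_sd = ratio.std(ddof=1)
        _, se2 = wald_ratio(0.1, 0.01, 0.05, 0.02, second_order=True)
        assert se2 == pytest.approx(mc_sd, rel=0.02)
        assert se2 == pytest.approx(math.sqrt(0.02**2 / 0.01 + 0.05**2 * 0.01**2 / 0.1**4))


class TestIvw:
    def test_single_snp_reduces_to_wald(self):
        h = make_hset([0.1], [0.01], [0.05], [0.02])
        res = ivw(h)
        est, se = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert res.estimate == pytest.approx(est)
        assert res.se == pytest.approx(se)
        assert res.q is None

    def test_hand_computed_weighted_mean_and_q(self):
        # ratios 0.5 (se 0.1) and 0.3 (se 0.2) via beta_x = 1
        h = make_hset([1.0, 1.0], [1e-6, 1e-6], [0.5, 0.3], [0.1, 0.2])
        res = ivw(h, effects="fixed")
        assert res.estimate == pytest.approx(0.46)
        assert res.se == pytest.approx(125**-0.5)
        assert res.q == pytest.approx(0.8)

    def test_identical_ratios_degenerate(self):
        h = make_hset([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20], [0.02] * 3)
        res = ivw(h)
        assert res.estimate == pytest.approx(0.5)
        assert res.q == pytest.approx(0.0, abs=1e-20)
        assert res.se == pytest.approx(res.meta["se_fixed"])  # scale floored at 1

    def test_random_effects_never_below_fixed(self):
        e, o, _ = simulate_two_sample(SimulationConfig(n_snps=30, theta=0.2, seed=1))
        h = HarmonizedSet.from_aligned(e, o)
        res = ivw(h)
        assert res.se >= res.meta["se_fixed"]

    def test_unknown_effects_flavor(self):
        h = make_hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(ValueError, match="flavor"):
            ivw(h, effects="additive")

    def test_ci_brackets_estimate_and_or_scale_consistency(self):
        e, o, _ = simulate_two_sample(SimulationConfig(n_snps=20, theta=0.1, seed=2))
        res = ivw(HarmonizedSet.from_aligned(e, o))
        assert res.ci_low <= res.estimate <= res.ci_high
        ors = res.or_scale()
        assert ors["ci_low"] == pytest.approx(math.exp(res.ci_low))
        assert ors["ci_high"] == pytest.approx(math.exp(res.ci_high))


class TestCochranQ:
    def test_arithmetic_q10_j6(self):
        # six unit-weight ratios, symmetric around 0, Q = 10 -> I2 = 50%
        a = math.sqrt(10 / 6)
        h = make_hset([1.0] * 6, [1e-8] * 6, [a, a, a, -a, -a, -a], [1.0] * 6)
        qr = cochran_q(h)
        assert qr.q == pytest.approx(10.0)
        assert qr.i2 == pytest.approx(50.0)

    def test_floor_at_zero(self):
        h = make_hset([1.0, 1.0, 1.0], [1e-8] * 3, [0.299, 0.3, 0.301], [1.0] * 3)
        qr = cochran_q(h)
        assert qr.q < 2
        assert qr.i2 == 0.0

    def test_requires_two_snps(self):
        with pytest.raises(ValueError):
            cochran_q(make_hset([0.1], [0.01], [0.05], [0.02]))

    def test_null_rejection_rate_calibrated(self):
        # no pleiotropy: Q ~ chi2(J-1), rejection at 0.05 near nominal
        rej = 0
        reps = 600
        for s in range(reps):
            e, o, _ = simulate_two_sample(
                SimulationConfig(n_snps=20, theta=0.1, seed=3000 + s)
            )
            rej += cochran_q(HarmonizedSet.from_aligned(e, o)).q_pval < 0.05
        assert 0.03 <= rej / reps <= 0.07


class TestMrEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.05, 0.08, 0.1, 0.12])
        h = make_hset(bx, [0.01] * 4, 0.3 * bx, [0.02] * 4)
        res = mr_egger(h)
        assert res.estimate == pytest.approx(0.3, abs=1e-10)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-10)

    def test_intercept_shift_recovered(self):
        bx = np.array([0.05, 0.08, 0.1, 0.12, 0.15])
        h = make_hset(bx, [0.01] * 5, 0.02 + 0.3 * bx, [0.02] * 5)
        res = mr_egger(h)
        assert res.egger_intercept == pytest.approx(0.02, abs=1e-10)
        assert res.estimate == pytest.approx(0.3, abs=1e-10)

    def test_orientation_invariance(self):
        bx = np.array([0.05, -0.08, 0.1, -0.12])
        by = np.array([0.015, -0.024, 0.03, -0.036]) + 0.001
        h1 = make_hset(bx, [0.01] * 4, by, [0.02] * 4)
        h2 = make_hset(-bx, [0.01] * 4, -by, [0.02] * 4)
        r1, r2 = mr_egger(h1), mr_egger(h2)
        assert r1.estimate == pytest.approx(r2.estimate)
        assert r1.egger_intercept == pytest.approx(r2.egger_intercept)

    def test_requires_three_snps(self):
        with pytest.raises(ValueError):
            mr_egger(make_hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2))

    def test_no_variation_in_beta_x_raises(self):
        with pytest.raises(ValueError, match="variation"):
            mr_egger(make_hset([0.1] * 4, [0.01] * 4, [0.03, 0.04, 0.02, 0.05], [0.02] * 4))

    def test_balanced_pleiotropy_intercept_type_i(self):
        rej = 0
        reps = 300
        for s in range(reps):
            e, o, _ = simulate_two_sample(
                SimulationConfig(
                    n_snps=50,
                    theta=0.2,
                    invalid_fraction=1.0,
                    pleiotropy_mean=0.0,
                    pleiotropy_sd=0.03,
                    seed=5000 + s,
                )
            )
            rej += mr_egger(HarmonizedSet.from_aligned(e, o)).intercept_pval < 0.05
        assert 0.02 <= rej / reps <= 0.09


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        h = make_hset([1.0, 1.0, 1.0], [1e-8] * 3, [0.4, 0.5, 0.6], [0.1] * 3)
        assert weighted_median(h, n_boot=0).estimate == pytest.approx(0.5)

    def test_degenerate_all_equal(self):
        h = make_hset([0.1, 0.2, 0.25], [0.001] * 3, [0.04, 0.08, 0.10], [0.002] * 3)
        r1 = weighted_median(h, n_boot=500, seed=1)
        r2 = weighted_median(h, n_boot=500, seed=2)
        assert r1.estimate == pytest.approx(0.4)
        assert r1.se < 0.05
        assert r1.se == pytest.approx(r2.se, rel=0.3)  # seed-independent up to MC error

    def test_seed_determinism(self):
        e, o, _ = simulate_two_sample(SimulationConfig(n_snps=10, theta=0.1, seed=4))
        h = HarmonizedSet.from_aligned(e, o)
        r1 = weighted_median(h, n_boot=300, seed=7)
        r2 = weighted_median(h, n_boot=300, seed=7)
        assert r1.se == r2.se

    def test_requires_three_snps(self):
        with pytest.raises(ValueError):
            weighted_median(make_hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2))

    def test_resists_invalid_instruments(self):
        # quick version of the robustness simulation (full run in acceptance)
        wm_est, ivw_est = [], []
        for s in range(100):
            e, o, _ = simulate_two_sample(
                SimulationConfig(
                    n_snps=50,
                    theta=0.3,
                    invalid_fraction=0.3,
                    pleiotropy_mean=0.15,
                    pleiotropy_sd=0.02,
                    seed=7000 + s,
                )
            )
            h = HarmonizedSet.from_aligned(e, o)
            wm_est.append(weighted_median(h, n_boot=0).estimate)
            ivw_est.append(ivw(h).estimate)
        assert abs(np.mean(wm_est) - 0.3) < abs(np.mean(ivw_est) - 0.3) / 3


class TestMaxLikelihood:
    def test_single_snp_equals_wald(self):
        h = make_hset([0.1], [0.01], [0.05], [0.02])
        res = max_likelihood(h)
        assert res.estimate == pytest.approx(0.5, abs=1e-6)

    def test_matches_fixed_ivw_for_homogeneous_data(self):
        rng = np.random.default_rng(7)
        j = 30
        g = rng.uniform(0.05, 0.1, j)
        sx, sy = np.full(j, 1e-4), np.full(j, 0.002)
        bx = g + rng.normal(0, 1, j) * sx
        by = 0.3 * g + rng.normal(0, 1, j) * sy
        h = make_hset(bx, sx, by, sy)
        assert max_likelihood(h).estimate == pytest.approx(
            ivw(h, effects="fixed").estimate, abs=1e-3
        )

    def test_theta_recovery(self):
        ests = []
        for s in range(120):
            e, o, _ = simulate_two_sample(
                SimulationConfig(n_snps=30, theta=0.3, seed=8000 + s)
            )
            ests.append(max_likelihood(HarmonizedSet.from_aligned(e, o)).estimate)
        ests = np.array(ests)
        mc_se = ests.std(ddof=1) / math.sqrt(len(ests))
        assert abs(ests.mean() - 0.3) < 2 * mc_se


class TestLeaveOneOut:
    def test_identical_snps_give_identical_rows(self):
        h = make_hset([0.1] * 4, [0.01] * 4, [0.05] * 4, [0.02] * 4)
        loo = leave_one_out(h)
        assert len(loo) == 4
        assert loo["estimate"].nunique() == 1
        full = ivw(h)
        assert loo["estimate"].iloc[0] == pytest.approx(full.estimate)

    def test_outlier_removal_moves_estimate_most(self):
        bx = np.full(8, 0.1)
        by = np.full(8, 0.05)
        by[3] += 0.2  # gross outlier
        h = make_hset(bx, [0.01] * 8, by, [0.02] * 8)
        loo = leave_one_out(h)
        assert loo["delta_estimate"].abs().idxmax() == 3

    def test_three_rows_for_three_snps(self):
        h = make_hset([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.15], [0.02] * 3)
        assert len(leave_one_out(h)) == 3

    def test_requires_three_snps(self):
        with pytest.raises(ValueError):
            leave_one_out(make_hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2))


@st.composite
def _harmonized_sets(draw):
    j = draw(st.integers(4, 12))
    rng = np.random.default_rng(draw(st.integers(0, 2**31)))
    bx = rng.uniform(0.03, 0.2, j) * rng.choice([-1, 1], j)
    return make_hset(
        bx,
        rng.uniform(0.005, 0.02, j),
        rng.normal(0.05, 0.05, j),
        rng.uniform(0.01, 0.05, j),
    )


class TestEstimatorProperties:
    @given(_harmonized_sets())
    @settings(max_examples=25, deadline=None)
    def test_negating_outcome_negates_estimates_keeps_ses(self, h):
        neg = make_hset(
            h.data["beta_x"], h.data["se_x"], -h.data["beta_y"], h.data["se_y"]
        )
        for fn in (lambda x: ivw(x), lambda x: mr_egger(x), lambda x: max_likelihood(x)):
            a, b = fn(h), fn(neg)
            assert b.estimate == pytest.approx(-a.estimate, rel=1e-6, abs=1e-9)
            assert b.se == pytest.approx(a.se, rel=1e-6)
        a = weighted_median(h, n_boot=0).estimate
        b = weighted_median(neg, n_boot=0).estimate
        assert b == pytest.approx(-a, rel=1e-9)

    @given(_harmonized_sets(), st.floats(0.2, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_scaling_exposure_scales_estimates_inversely(self, h, c):
        scaled = make_hset(
            c * h.data["beta_x"], c * h.data["se_x"], h.data["beta_y"], h.data["se_y"]
        )
        assert ivw(scaled).estimate == pytest.approx(ivw(h).estimate / c, rel=1e-9)
        assert weighted_median(scaled, n_boot=0).estimate == pytest.approx(
            weighted_median(h, n_boot=0).estimate / c, rel=1e-9
        )

    def test_egger_through_origin_equals_ivw(self):
        # constraining the Egger intercept to zero reproduces the IVW slope
        e, o, _ = simulate_two_sample(SimulationConfig(n_snps=25, theta=0.2, seed=9))
        h = HarmonizedSet.from_aligned(e, o)
        bx, _, by, sy = h.arrays()
        w = 1.0 / sy**2
        slope_origin = (w * bx * by).sum() / (w * bx * bx).sum()
        assert ivw(h).estimate == pytest.approx(slope_origin, rel=1e-12)
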