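"""Closed-form Poisson layer: estimator, CI, precision, windows, partition counts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpcrtools import (
    ChipDesign,
    ConfidenceSpec,
    InvalidInputError,
    PartitionCounts,
    SaturatedChipError,
    UnachievablePrecisionError,
    confidence_interval,
    detection_limits_at_precision,
    estimate_lambda,
    lambda_to_concentration,
    min_partitions_for_precision,
    optimal_lambda,
    precision,
    sampling_sigma,
    theoretical_detection_limits,
)

Z196 = ConfidenceSpec(strict_paper=True)


class TestEstimateLambda:
    @pytest.mark.parametrize(
        "z, n, expected",
        [
            (20000, 20000, 0.0),
            (2032, 10000, -math.log(0.2032)),
            (5000, 10000, math.log(2)),
        ],
    )
    def test_mle_values(self, z, n, expected):
        assert estimate_lambda(PartitionCounts(n=n, negatives=z)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_saturated_chip_raises(self):
        with pytest.raises(SaturatedChipError):
            estimate_lambda(PartitionCounts(n=10000, negatives=0))

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            PartitionCounts(n=10, negatives=11)
        with pytest.raises(InvalidInputError):
            PartitionCounts(n=0, negatives=0)

    @pytest.mark.parametrize("n", [5, 17, 50])
    def test_matches_binomial_likelihood_argmax(self, n):
        """The −ln(z/n) estimator maximises the exact binomial likelihood."""
        grid = np.linspace(1e-6, 8.0, 400001)
        log_q = -grid
        log_p = np.log1p(-np.exp(-grid))
        for z in range(1, n):
            loglik = z * log_q + (n - z) * log_p
            oracle = grid[np.argmax(loglik)]
            mle = estimate_lambda(PartitionCounts(n=n, negatives=z))
            assert mle == pytest.approx(oracle, abs=1e-4)


class TestConcentration:
    def test_zero_and_identity(self):
        design = ChipDesign(n=100, partition_volume=1.0)
        assert lambda_to_concentration(0.0, design) == 0.0
        assert lambda_to_concentration(1.0, design) == 1.0

    def test_865pl_partition(self):
        design = ChipDesign(n=20000, partition_volume=8.65e-4)
        assert lambda_to_concentration(1.5936, design) == pytest.approx(1842.3, rel=1e-4)

    def test_negative_lambda_rejected(self):
        with pytest.raises(InvalidInputError):
            lambda_to_concentration(-0.1, ChipDesign(n=10, partition_volume=1.0))


class TestSamplingSigma:
    def test_reference_value(self):
        assert sampling_sigma(1.5936, 20000) == pytest.approx(0.008787, abs=5e-7)

    def test_inverse_sqrt_n_scaling(self):
        assert sampling_sigma(1.5936, 80000) == pytest.approx(
            sampling_sigma(1.5936, 20000) / 2, rel=1e-12
        )

    def test_small_lambda_limit(self):
        # e^λ − 1 → λ, so σ → 1/sqrt(λ n)
        assert sampling_sigma(1e-4, 10**6) == pytest.approx(0.100003, abs=1e-6)

    @given(
        lam=st.floats(1e-3, 10.0),
        n=st.integers(1, 10**6),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_q_form_equivalence(self, lam, n):
        """σ via the negative-fraction form equals the λ form to 1e-12 relative."""
        q = math.exp(-lam)
        q_form = math.sqrt(1 - q) / (abs(math.log(q)) * math.sqrt(n * q))
        assert sampling_sigma(lam, n) == pytest.approx(q_form, rel=1e-12)


class TestConfidenceInterval:
    def test_reference_interval(self):
        lo, hi = confidence_interval(1.5936, 20000, Z196)
        assert lo == pytest.approx(1.5664, abs=5e-5)
        assert hi == pytest.approx(1.6213, abs=5e-5)

    def test_zero_z_degenerates(self):
        lo, hi = confidence_interval(2.0, 1000, ConfidenceSpec(z_score=0.0))
        assert lo == hi == 2.0

    @given(lam=st.floats(0.01, 8.0), n=st.integers(100, 10**6))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_multiplicative_symmetry_and_asymmetry(self, lam, n):
        lo, hi = confidence_interval(lam, n)
        assert hi / lam == pytest.approx(lam / lo, rel=1e-9)
        # additively, the upper side is at least as wide
        assert (hi - lam) >= (lam - lo) - 1e-15


class TestPrecision:
    def test_reference_values(self):
        assert precision(1.5936, 20000, Z196) == pytest.approx(0.01737, abs=5e-6)
        assert precision(0.0058, 20000, Z196) == pytest.approx(0.1999, abs=5e-4)

    def test_quadrupling_n_halves_log_precision(self):
        p1 = precision(0.8, 20000)
        p4 = precision(0.8, 80000)
        assert math.log1p(p4) == pytest.approx(math.log1p(p1) / 2, rel=1e-12)

    @pytest.mark.parametrize("lam", [0.05, 1.5936, 6.0])
    def test_strictly_decreasing_in_n(self, lam):
        values = [precision(lam, n) for n in (100, 1000, 10000, 100000)]
        assert all(a > b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("n", [1000, 20000, 10**6])
    def test_argmin_at_optimal_lambda(self, n):
        """Grid scan confirms the precision minimum sits at λ* for any n."""
        lam_star, _ = optimal_lambda()
        grid = np.linspace(0.05, 6.0, 2000)
        values = [precision(l, n) for l in grid]
        assert grid[int(np.argmin(values))] == pytest.approx(lam_star, abs=5e-3)

    def test_deteriorates_faster_above_optimum(self):
        lam_star, _ = optimal_lambda()
        for r in (1.5, 2.0, 3.0):
            assert precision(lam_star * r, 20000) > precision(lam_star / r, 20000)


class TestOptimalLambda:
    def test_fixed_point_and_negative_fraction(self):
        lam_star, q_star = optimal_lambda()
        assert lam_star == pytest.approx(1.5936, abs=5e-5)
        assert lam_star == pytest.approx(2 * (1 - math.exp(-lam_star)), abs=1e-12)
        assert q_star == pytest.approx(0.2032, abs=5e-5)


class TestTheoreticalLimits:
    def test_single_partition(self):
        win = theoretical_detection_limits(1, 0.05)
        assert win.lambda_low == pytest.approx(0.05129, abs=5e-6)
        assert win.lambda_high == pytest.approx(2.9957, abs=5e-5)

    def test_20k_partitions(self):
        win = theoretical_detection_limits(20000, 0.05)
        assert win.lambda_low == pytest.approx(2.5647e-6, rel=1e-4)
        assert win.lambda_high == pytest.approx(12.874, abs=5e-3)
        assert win.dynamic_range == pytest.approx(6.70, abs=5e-3)

    def test_lower_limit_vanishes_with_alpha(self):
        limits = [theoretical_detection_limits(100, a).lambda_low for a in (0.1, 0.01, 0.001)]
        assert all(a > b for a, b in zip(limits, limits[1:]))

    def test_invalid_alpha(self):
        with pytest.raises(InvalidInputError):
            theoretical_detection_limits(100, 1.5)


class TestDetectionLimitsAtPrecision:
    def test_fig7_baseline_lod(self):
        win = detection_limits_at_precision(20000, 0.20, Z196)
        assert round(win.lambda_low, 3) == 0.006

    def test_ten_percent_window(self):
        win = detection_limits_at_precision(20000, 0.10, Z196)
        assert win.lambda_low == pytest.approx(0.0212, abs=2e-4)
        assert win.lambda_high == pytest.approx(8.03, abs=2e-2)
        assert win.dynamic_range == pytest.approx(2.574, abs=2e-3)

    @pytest.mark.parametrize("bound", [0.05, 0.10, 0.20])
    def test_roots_satisfy_precision_equation(self, bound):
        win = detection_limits_at_precision(20000, bound)
        for root in (win.lambda_low, win.lambda_high):
            assert abs(precision(root, 20000) - bound) <= 1e-9 * bound

    def test_unachievable_precision_reports_minimum(self):
        with pytest.raises(UnachievablePrecisionError) as exc:
            detection_limits_at_precision(20000, 0.001)
        assert exc.value.minimum == pytest.approx(0.0174, abs=2e-4)


class TestMinPartitions:
    def test_defining_inequality_at_optimum(self):
        lam_star, _ = optimal_lambda()
        n = min_partitions_for_precision(lam_star, 0.05, Z196)
        assert precision(lam_star, n, Z196) <= 0.05 < precision(lam_star, n - 1, Z196)
        assert n == 2492

    def test_minimised_at_optimal_lambda(self):
        lam_star, _ = optimal_lambda()
        n_star = min_partitions_for_precision(lam_star, 0.05)
        for lam in (0.3, 0.8, 2.5, 4.0):
            assert min_partitions_for_precision(lam, 0.05) >= n_star

    def test_loose_precision_needs_one_partition(self):
        # precision(1.0, n=1) ≈ 12.05, so any looser bound is met by one partition
        assert min_partitions_for_precision(1.0, 15.0) == 1
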