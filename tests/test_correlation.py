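"""Unit tests for the two-point correlation estimator and diameter fit."""

import numpy as np
import pytest

from segdyn.correlation import (
    CorrelationCurve,
    binarize_channel,
    brute_force_correlation,
    cluster_size_series,
    combine_replicates,
    fit_cluster_diameter,
    two_point_correlation,
)
from segdyn.stack import BinaryMask3D, VoxelStack

from conftest import random_mask, two_channel_stack


def quadratic_curve(K, R0, r):
    return K * (1.5 * R0**2 - 2.0 * R0 * r + 0.5 * r**2)


class TestTwoPointCorrelation:
    def test_zero_separation_bin_is_indicator_variance(self, rng):
        mask = random_mask(rng, (6, 24, 24), p=0.4)
        curve = two_point_correlation(mask, r_max=12, bin_width=1.0)
        p = mask.occupied_fraction
        assert curve.C[0] == pytest.approx(p * (1 - p), rel=1e-12)

    def test_raw_curve_zero_bin_is_marginal(self, rng):
        mask = random_mask(rng, (6, 24, 24), p=0.4)
        curve = two_point_correlation(mask, r_max=12, bin_width=1.0, connected=False)
        assert curve.C[0] == pytest.approx(mask.occupied_fraction, rel=1e-12)

    def test_matches_brute_force_small(self, rng):
        mask = random_mask(rng, (4, 12, 12), p=0.3)
        fft = two_point_correlation(mask, r_max=15, bin_width=1.5)
        ref = brute_force_correlation(mask, r_max=15, bin_width=1.5)
        np.testing.assert_array_equal(fft.pair_counts, ref.pair_counts)
        valid = fft.valid
        np.testing.assert_allclose(fft.C[valid], ref.C[valid], atol=1e-12)

    def test_anisotropic_spacing_measures_micrometres(self):
        # Two occupied voxels separated by one z step of 10 µm must
        # correlate in the r = 10 µm bin, not the r = 1 bin.
        m = np.zeros((3, 5, 5), dtype=bool)
        m[0, 2, 2] = m[1, 2, 2] = True
        mask = BinaryMask3D(m, (10.0, 1.0, 1.0))
        curve = two_point_correlation(mask, r_max=12, bin_width=1.0, connected=False)
        i10 = np.argmin(np.abs(curve.r_centers - 10.0))
        # raw E[phi phi] at 10 µm: 2 ordered pairs over the pair count there
        assert curve.C[i10] > 0
        i1 = np.argmin(np.abs(curve.r_centers - 1.0))
        assert curve.C[i1] == 0

    def test_r_max_beyond_box_warns(self, rng):
        mask = random_mask(rng, (4, 12, 12), p=0.3)
        with pytest.warns(UserWarning, match="r_max"):
            two_point_correlation(mask, r_max=500.0, bin_width=2.0)

    def test_pair_counts_total(self, rng):
        # Summed ordered pair counts over all bins equal n² when r_max
        # covers the whole box diagonal.
        m = np.zeros((1, 6, 6), dtype=bool)
        m[0, :3, :3] = True
        mask = BinaryMask3D(m, (1.0, 1.0, 1.0))
        with pytest.warns(UserWarning, match="r_max"):
            curve = two_point_correlation(mask, r_max=10.0, bin_width=0.5)
        n = m.size
        assert curve.pair_counts.sum() == n * n


class TestFitClusterDiameter:
    def test_noiseless_recovery_machine_precision(self):
        K, R0 = 2.0, 50.0
        r = np.arange(0, 120.0, 2.0)
        curve = CorrelationCurve(
            r_centers=r,
            C=quadratic_curve(K, R0, r),
            pair_counts=np.full(r.size, 1000),
            r_max=120.0,
            bin_width=2.0,
            p=0.3,
        )
        fit = fit_cluster_diameter(curve)
        assert fit.converged
        assert fit.R0 == pytest.approx(R0, rel=1e-6)
        assert fit.K == pytest.approx(K, rel=1e-6)

    def test_default_window_stops_at_first_zero_crossing(self):
        K, R0 = 1.0, 30.0
        r = np.arange(0, 100.0, 2.0)
        C = quadratic_curve(K, R0, r)
        C[r > R0] = 0.05  # junk beyond the crossing must not matter
        curve = CorrelationCurve(r, C, np.full(r.size, 100), 100.0, 2.0, 0.3)
        fit = fit_cluster_diameter(curve)
        assert fit.R0 == pytest.approx(R0, rel=1e-3)
        assert fit.fit_range[1] <= R0 + 2.0

    def test_range_limited_flag(self):
        K, R0 = 2.0, 50.0
        r = np.arange(0, 46.0, 1.0)  # window ends before r = R0
        curve = CorrelationCurve(
            r, quadratic_curve(K, R0, r), np.full(r.size, 100), 46.0, 1.0, 0.3
        )
        with pytest.warns(UserWarning):
            fit = fit_cluster_diameter(curve)
        assert fit.range_limited
        assert fit.R0 == pytest.approx(R0, rel=1e-4)

    def test_rejects_too_few_bins(self):
        r = np.arange(0, 3.0, 1.0)
        curve = CorrelationCurve(r, np.ones(3), np.full(3, 10), 3.0, 1.0, 0.3)
        with pytest.raises(ValueError):
            fit_cluster_diameter(curve, fit_range=(0.0, 2.0))


class TestBinarize:
    def test_fixed_threshold(self, rng):
        stack = two_channel_stack(rng)
        mask = binarize_channel(stack, "A", method="fixed", fixed_value=100.0)
        np.testing.assert_array_equal(
            mask.mask, np.asarray(stack.channels["A"]) > 100.0
        )

    def test_otsu_separates_bimodal(self, rng):
        stack = two_channel_stack(rng)
        mask = binarize_channel(stack, "A", method="otsu")
        truth = np.asarray(stack.channels["A"]) > 100.0
        agreement = (mask.mask == truth).mean()
        assert agreement > 0.999

    def test_constant_channel_rejected(self):
        stack = VoxelStack(
            channels={"A": np.full((2, 8, 8), 7.0)}, spacing=(10.0, 1.0, 1.0)
        )
        with pytest.raises(ValueError, match="constant"):
            binarize_channel(stack, "A", method="otsu")


class TestSeries:
    def test_failed_fit_yields_nan_not_crash(self, rng):
        good = two_channel_stack(rng, timestamp=0.0)
        # A constant channel cannot be auto-thresholded: that time point
        # must come back NaN while the rest of the series survives.
        bad = VoxelStack(
            channels={
                "A": np.full((4, 32, 32), 5.0),
                "B": np.asarray(two_channel_stack(rng).channels["B"]),
            },
            spacing=(10.0, 1.0, 1.0),
            timestamp=1.0,
        )
        series = cluster_size_series([good, bad], ["A"], r_max=30, bin_width=1.0)
        assert np.isnan(series.R0["A"][1])

    def test_combine_replicates_mean_and_sem(self):
        from segdyn.correlation import ClusterSizeSeries

        s1 = ClusterSizeSeries(times=[0.0, 1.0], R0={"A": np.array([10.0, 20.0])})
        s2 = ClusterSizeSeries(times=[0.0, 1.0], R0={"A": np.array([14.0, 24.0])})
        combined = combine_replicates([s1, s2])
        np.testing.assert_allclose(combined.R0["A"], [12.0, 22.0])
        np.testing.assert_allclose(combined.sem["A"], [2.0, 2.0])
        assert combined.replicate_count == 2
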