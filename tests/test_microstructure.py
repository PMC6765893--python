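"""Angular-profile processing: normalisation, folding, reduction, trends."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fibreo import synthetic as syn
from fibreo.microstructure import (
    AngularProfile,
    AsymmetryWarning,
    DegenerateSeriesWarning,
    DeltaDistribution,
    EmptyScanError,
    FibrilDistribution,
    RegionMap,
    StrainSeries,
    average_regions,
    delta_density,
    fit_trend,
    fold_to_axes,
    normalize_total,
    profile_to_distribution,
    reduce_orientations,
    symmetrize,
)
from fibreo.orientations import N_AXES, N_ORIENTATIONS, N_READINGS, SYMMETRIC_PAIRS

RNG = np.random.default_rng(42)


def symmetric_profile(rng, total=100.0):
    half = rng.uniform(0.1, 1.0, N_AXES)
    d = np.concatenate([half, half])
    return AngularProfile(d * total / d.sum())


# ----------------------------------------------------------------------
# normalisation
# ----------------------------------------------------------------------
class TestNormalizeTotal:
    def test_uniform_profile(self):
        out = normalize_total(AngularProfile(np.full(N_READINGS, 2.0)))
        assert np.allclose(out.densities, 1.0 / N_READINGS, atol=1e-15)
        assert abs(out.densities.sum() - 1.0) < 1e-12

    def test_total_equated_to_one(self):
        d = RNG.uniform(0, 1, N_READINGS)
        d *= 37.4 / d.sum()
        out = normalize_total(AngularProfile(d))
        assert abs(out.densities.sum() - 1.0) < 1e-12

    def test_scale_invariance(self):
        d = RNG.uniform(0.1, 1, N_READINGS)
        a = normalize_total(AngularProfile(d))
        b = normalize_total(AngularProfile(3.7 * d))
        np.testing.assert_allclose(a.densities, b.densities, rtol=0, atol=1e-15)

    def test_empty_scan_rejected(self):
        with pytest.raises(EmptyScanError):
            normalize_total(AngularProfile(np.zeros(N_READINGS)))

    @settings(max_examples=25, deadline=None)
    @given(arrays(float, N_READINGS, elements=st.floats(0.01, 1e3)))
    def test_shape_preserved(self, d):
        out = normalize_total(AngularProfile(d))
        ratio = out.densities / d
        assert np.allclose(ratio, ratio[0], rtol=1e-12)


# ----------------------------------------------------------------------
# folding to the 128 unique axes
# ----------------------------------------------------------------------
class TestFoldToAxes:
    def test_point_symmetric_scan_has_128_unique_axes(self):
        p = symmetric_profile(RNG)
        axial = fold_to_axes(p)
        assert axial.shape == (N_AXES,)
        np.testing.assert_allclose(axial, p.densities[:N_AXES], atol=1e-15)

    def test_uniform_profile(self):
        axial = fold_to_axes(AngularProfile(np.ones(N_READINGS)))
        assert np.allclose(axial, 1.0)

    def test_single_perturbed_pair_moves_one_axis(self):
        p = symmetric_profile(RNG)
        d = p.densities.copy()
        d[17] += 0.1
        d[17 + N_AXES] += 0.1
        axial = fold_to_axes(AngularProfile(d))
        # independent oracle: explicit pairing loop
        expected = np.array([(d[j] + d[j + N_AXES]) / 2 for j in range(N_AXES)])
        np.testing.assert_allclose(axial, expected, atol=1e-15)
        base = fold_to_axes(p)
        changed = np.nonzero(np.abs(axial - base) > 1e-14)[0]
        assert changed.tolist() == [17]

    def test_asymmetry_warns_but_folds(self):
        d = np.ones(N_READINGS)
        d[:N_AXES] = 2.0
        with pytest.warns(AsymmetryWarning):
            axial = fold_to_axes(AngularProfile(d))
        assert np.allclose(axial, 1.5)


# ----------------------------------------------------------------------
# 128 -> 16 reduction
# ----------------------------------------------------------------------
class TestReduceOrientations:
    def test_uniform(self):
        K = reduce_orientations(np.ones(N_AXES))
        assert np.allclose(K.K, 8.0)

    def test_delta_spike_support(self):
        axial = np.zeros(N_AXES)
        axial[37] = 5.0
        K = reduce_orientations(axial)
        assert K.K[37 // 8] == 5.0
        assert K.K.sum() == 5.0

    def test_content_conserved_against_bruteforce(self):
        axial = RNG.uniform(0, 1, N_AXES)
        K = reduce_orientations(axial)
        # brute-force summation oracle
        expected = [sum(axial[8 * i + j] for j in range(8)) for i in range(16)]
        np.testing.assert_allclose(K.K, expected, rtol=1e-14)
        assert abs(K.K.sum() - axial.sum()) < 1e-12

    def test_non_divisor_rejected(self):
        with pytest.raises(ValueError):
            reduce_orientations(np.ones(N_AXES), n=7)

    @settings(max_examples=25, deadline=None)
    @given(arrays(float, N_AXES, elements=st.floats(0.0, 100.0)), st.floats(0.1, 10.0))
    def test_commutes_with_scaling(self, axial, c):
        a = reduce_orientations(c * axial).K
        b = c * reduce_orientations(axial).K
        np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-9)


# ----------------------------------------------------------------------
# density changes and symmetry averaging
# ----------------------------------------------------------------------
class TestDeltaAndSymmetrize:
    def test_identity_gives_zero(self):
        K = FibrilDistribution(RNG.uniform(0.1, 1, 16), "raw")
        d = delta_density(K, K)
        assert np.all(d.dK == 0)

    def test_equal_totals_sum_to_zero(self):
        a = RNG.uniform(0.1, 1, 16)
        b = RNG.uniform(0.1, 1, 16)
        b *= a.sum() / b.sum()
        d = delta_density(FibrilDistribution(a, "raw"), FibrilDistribution(b, "raw"))
        assert abs(d.dK.sum() - (a.sum() - b.sum())) < 1e-12
        d2 = delta_density(FibrilDistribution(b, "raw"), FibrilDistribution(a, "raw"))
        assert abs(d2.dK.sum()) < 1e-10

    def test_elementwise_difference(self):
        a = np.arange(16.0)
        b = np.ones(16)
        d = delta_density(FibrilDistribution(a, "raw"), FibrilDistribution(b, "raw"))
        np.testing.assert_array_equal(d.dK, a - b)

    def test_mismatched_normalisation_rejected(self):
        a = FibrilDistribution(np.ones(16) / 16, "total_one")
        b = FibrilDistribution(np.ones(16), "mean_one")
        with pytest.raises(ValueError):
            delta_density(a, b)

    def test_symmetrize_pair_mean_example(self):
        dk = np.zeros(16)
        dk[0] = 1.0
        dk[15] = 3.0
        out = symmetrize(DeltaDistribution(dk, 0.05))
        assert out.dK[0] == out.dK[15] == 2.0
        assert np.all(out.dK[1:15] == 0)

    def test_symmetrize_is_idempotent_and_conserving(self):
        dk = RNG.standard_normal(16)
        once = symmetrize(DeltaDistribution(dk, 0.0))
        twice = symmetrize(once)
        np.testing.assert_array_equal(once.dK, twice.dK)
        assert abs(once.dK.sum() - dk.sum()) < 1e-12
        assert len(np.unique(np.round(once.dK, 12))) <= 8
        # explicit pair-loop oracle
        expected = dk.copy()
        for m, n in SYMMETRIC_PAIRS:
            expected[m] = expected[n] = 0.5 * (dk[m] + dk[n])
        np.testing.assert_allclose(once.dK, expected, atol=1e-15)


# ----------------------------------------------------------------------
# region averaging
# ----------------------------------------------------------------------
class TestAverageRegions:
    def test_identical_points(self):
        K = FibrilDistribution(RNG.uniform(0.5, 2, 16), "raw")
        regions = average_regions([FibrilDistribution(K.K.copy(), "raw")] * 40)
        for r in "ABC":
            np.testing.assert_allclose(regions[r].K, K.K)

    def test_symmetric_group_mean(self):
        points = [FibrilDistribution(np.ones(16), "raw") for _ in range(40)]
        for p in range(0, 8):
            points[p] = FibrilDistribution(np.full(16, 0.8), "raw")
        for p in range(32, 40):
            points[p] = FibrilDistribution(np.full(16, 1.2), "raw")
        regions = average_regions(points)
        np.testing.assert_allclose(regions["A"].K, 1.0)

    def test_against_flat_bruteforce(self):
        data = RNG.uniform(0.2, 2, (40, 16))
        points = [FibrilDistribution(row, "raw") for row in data]
        regions = average_regions(points)
        np.testing.assert_allclose(regions["A"].K, data[list(range(8)) + list(range(32, 40))].mean(axis=0))
        np.testing.assert_allclose(regions["B"].K, data[list(range(8, 16)) + list(range(24, 32))].mean(axis=0))
        np.testing.assert_allclose(regions["C"].K, data[16:24].mean(axis=0))

    def test_wrong_point_count_rejected(self):
        with pytest.raises(ValueError):
            average_regions([FibrilDistribution(np.ones(16), "raw")] * 39)

    def test_region_map_involution(self):
        rm = RegionMap()
        assert sorted(sum((rm.points_in_region(r) for r in "ABC"), [])) == list(range(40))
        assert rm.region_of_group(1) == rm.region_of_group(5) == "A"
        assert rm.region_of_group(2) == rm.region_of_group(4) == "B"


# ----------------------------------------------------------------------
# trend fitting
# ----------------------------------------------------------------------
class TestFitTrend:
    def test_zero_change_series_yields_zero_trend(self):
        K0 = FibrilDistribution(np.ones(16), "mean_one")
        series = StrainSeries(
            [0.0, 0.014, 0.028, 0.05, 0.08],
            [FibrilDistribution(np.ones(16), "mean_one") for _ in range(5)],
        )
        with pytest.warns(DegenerateSeriesWarning):
            trend = fit_trend(series)
        assert np.all(trend.slope_mid == 0) and np.all(trend.slope_high == 0)

    def test_noise_free_round_trip_recovers_generator(self, fixture_trend):
        spec = syn.SeriesSpec(base=syn.noise_free(syn.ProfileSpec()), n_specimens=1)
        series = syn.gen_series(spec, fixture_trend)
        fitted = fit_trend(series)
        scale = np.abs(fixture_trend.slope_mid).max()
        np.testing.assert_allclose(fitted.slope_mid, fixture_trend.slope_mid, atol=1e-8 * scale)
        np.testing.assert_allclose(fitted.slope_high, fixture_trend.slope_high, atol=1e-8 * scale)

    def test_fitted_trend_is_zero_below_threshold(self, fixture_trend):
        spec = syn.SeriesSpec(base=syn.noise_free(syn.ProfileSpec()), n_specimens=1)
        fitted = fit_trend(syn.gen_series(spec, fixture_trend))
        assert np.all(fitted.evaluate(0.005) == 0.0)

    def test_insufficient_strain_span_rejected(self):
        dists = [FibrilDistribution(np.ones(16), "mean_one") for _ in range(2)]
        with pytest.raises(ValueError):
            fit_trend(StrainSeries([0.0, 0.014], dists))


def test_pipeline_profile_to_distribution_total_one():
    prof = syn.gen_profile(syn.noise_free(syn.ProfileSpec()))
    K = profile_to_distribution(prof, "total_one")
    assert abs(K.K.sum() - 1.0) < 1e-12
    K2 = profile_to_distribution(prof, "mean_one")
    assert abs(K2.K.mean() - 1.0) < 1e-12
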