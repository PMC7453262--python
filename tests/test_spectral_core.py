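"""Unit and property tests for the spectral axis / calibration / balancing chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pushbroom.errors import BalancingError, CalibrationError
from pushbroom.spectral_core import (
    CalibratedFrame,
    RawFrame,
    ReferenceSet,
    WavelengthGrid,
    bin_frame,
    build_wavelength_grid,
    compute_absorbance,
    compute_reflectance,
    fit_spectral_calibration,
    map_spectral_axis,
)


class TestWavelengthGrid:
    @pytest.mark.parametrize(
        "n,lo,hi,first,last,spacing",
        [
            (100, 500.0, 1000.0, 500.0, 995.0, 5.0),
            (1, 500.0, 505.0, 500.0, 500.0, 5.0),
            (500, 500.0, 1000.0, 500.0, 999.0, 1.0),
        ],
    )
    def test_grid_construction(self, n, lo, hi, first, last, spacing):
        grid = build_wavelength_grid(n, lo, hi)
        assert grid.n_channels == n
        assert grid.centers[0] == pytest.approx(first)
        assert grid.centers[-1] == pytest.approx(last)
        assert grid.spacing == pytest.approx(spacing)

    @pytest.mark.parametrize("args", [(0, 500, 1000), (100, 1000, 500), (10, 500, 500)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            build_wavelength_grid(*args)

    def test_non_uniform_centers_rejected(self):
        with pytest.raises(ValueError):
            WavelengthGrid(np.array([500.0, 505.0, 515.0]))


class TestSpectralCalibration:
    def test_exact_linear_anchor_recovery(self):
        pixels = np.array([10.0, 120.0, 390.0, 500.0, 700.0])
        anchors = [(p, 500.0 + 0.641 * p) for p in pixels]
        cal = fit_spectral_calibration(anchors, degree=1)
        assert np.max(np.abs(cal.residuals_nm)) <= 1e-9
        assert cal.coeffs[0] == pytest.approx(500.0, abs=1e-9)
        assert cal.coeffs[1] == pytest.approx(0.641, abs=1e-12)

    def test_quadratic_round_trip(self):
        # Anchors generated from a stated monotone quadratic must be
        # reproduced to numerical precision by a degree-2 fit.
        pixels = np.array([5.0, 100.0, 250.0, 420.0, 600.0, 779.0])
        anchors = [(p, 500.0 + 0.6 * p + 1e-5 * p**2) for p in pixels]
        cal = fit_spectral_calibration(anchors, degree=2)
        assert np.max(np.abs(cal.residuals_nm)) <= 1e-6
        assert cal.is_monotone()

    def test_jittered_krypton_anchors_residual_matches_noise(self):
        # Pixel jitter of sigma = 0.2 px should leave an RMS anchor residual
        # no larger than the jitter itself (in pixel-equivalent units);
        # with 7 anchors and 3 fit parameters the expectation is
        # sigma * sqrt((n - p)/n) ~ 0.15 px.
        true = lambda p: 500.0 + 0.62 * p + 2e-5 * p**2
        line_px = np.array([90.0, 140.0, 405.0, 420.0, 445.0, 497.0, 588.0])
        dispersion = 0.62  # nm per pixel, to convert residuals to px
        rms_px = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            jittered = line_px + rng.normal(0.0, 0.2, line_px.size)
            anchors = [(p, true(t)) for p, t in zip(jittered, line_px)]
            cal = fit_spectral_calibration(anchors, degree=2)
            rms_px.append(np.sqrt(np.mean(cal.residuals_nm**2)) / dispersion)
        assert np.mean(rms_px) <= 0.2

    def test_insufficient_anchors_rejected(self):
        with pytest.raises(ValueError):
            fit_spectral_calibration([(0, 500.0), (100, 560.0)], degree=2)

    def test_non_monotone_fit_rejected(self):
        anchors = [(p, 700.0 - 0.5 * p + 1e-3 * p**2) for p in (0, 100, 300, 700)]
        with pytest.raises(CalibrationError):
            fit_spectral_calibration(anchors, degree=2)

    def test_text_round_trip(self):
        anchors = [(10.0, 506.4), (700.0, 948.7)]
        cal = fit_spectral_calibration(anchors, degree=1)
        restored = type(cal).from_text(cal.to_text())
        np.testing.assert_allclose(restored.coeffs, cal.coeffs)
        assert restored.n_pixels == cal.n_pixels


class TestMapSpectralAxis:
    grid500 = build_wavelength_grid(500, 500.0, 1000.0)

    def _identity_cal(self):
        # pixel k maps exactly to channel k; pixels >= 500 fall past the grid
        from pushbroom.spectral_core import SpectralCalibration

        return SpectralCalibration(coeffs=np.array([500.0, 1.0]), n_pixels=780)

    def test_identity_assignment_preserves_in_range_pixels(self):
        cal = self._identity_cal()
        rng = np.random.default_rng(0)
        frame = RawFrame(rng.uniform(0, 100, (4, 780)))
        with pytest.warns(RuntimeWarning):
            out = map_spectral_axis(frame, cal, self.grid500)
        # channels 0..498 receive exactly pixel k; 499 also collects clipped pixels
        np.testing.assert_allclose(
            out.intensities[:, :499], frame.intensities[:, :499]
        )

    def test_constant_frame_maps_to_constant(self):
        cal = self._identity_cal()
        frame = RawFrame(np.full((3, 780), 7.0))
        with pytest.warns(RuntimeWarning):
            out = map_spectral_axis(frame, cal, self.grid500)
        np.testing.assert_allclose(out.intensities, 7.0)

    def test_shared_channel_pixels_are_averaged(self):
        from pushbroom.spectral_core import SpectralCalibration

        cal = SpectralCalibration(coeffs=np.array([500.0, 0.4]), n_pixels=2)
        frame = RawFrame(np.array([[4.0, 6.0]]))
        out = map_spectral_axis(frame, cal, self.grid500)
        assert out.intensities[0, 0] == pytest.approx(5.0)


class TestBinFrame:
    grid500 = build_wavelength_grid(500, 500.0, 1000.0)

    def test_constant_input_shape_and_value(self):
        frame = CalibratedFrame(np.full((960, 500), 3.5), self.grid500)
        out = bin_frame(frame)
        assert out.intensities.shape == (480, 100)
        np.testing.assert_allclose(out.intensities, 3.5)
        assert out.grid.spacing == pytest.approx(5.0)

    def test_spatial_pair_average(self):
        arr = np.full((2, 5), 1.0)
        arr[0, :] = 2.0
        arr[1, :] = 4.0
        frame = CalibratedFrame(arr, build_wavelength_grid(5, 500, 505))
        out = bin_frame(frame, spatial_factor=2, spectral_factor=5)
        assert out.intensities[0, 0] == pytest.approx(3.0)

    def test_non_divisible_shape_rejected(self):
        frame = CalibratedFrame(np.zeros((7, 500)), self.grid500)
        with pytest.raises(ValueError):
            bin_frame(frame)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        ns=st.integers(1, 6),
        nc=st.integers(1, 8),
        seed=st.integers(0, 1000),
    )
    def test_binning_preserves_grand_mean(self, ns, nc, seed):
        rng = np.random.default_rng(seed)
        arr = rng.uniform(0, 50, (2 * ns, 5 * nc))
        frame = CalibratedFrame(arr, build_wavelength_grid(5 * nc, 500, 500 + 5 * nc))
        out = bin_frame(frame, 2, 5)
        assert out.intensities.mean() == pytest.approx(arr.mean(), rel=1e-12)


class TestBalancing:
    def _ref(self, ns=6, nc=10, dark_level=10.0, white_level=50.0):
        dark = np.full((ns, nc), dark_level)
        white = np.full((ns, nc), white_level)
        return ReferenceSet(dark=dark, white=white, distance_cm=5.0)

    def test_white_input_gives_unity(self):
        ref = self._ref()
        cube = compute_reflectance(ref.white[None], ref)
        np.testing.assert_allclose(cube.values, 1.0)
        assert cube.mask.all()

    def test_dark_input_gives_zero(self):
        ref = self._ref()
        cube = compute_reflectance(ref.dark[None], ref)
        np.testing.assert_allclose(cube.values, 0.0)

    def test_midpoint_value(self):
        ref = self._ref(dark_level=10.0, white_level=50.0)
        cube = compute_reflectance(np.full((1, 6, 10), 30.0), ref)
        np.testing.assert_allclose(cube.values, 0.5)

    def test_identity_for_random_references(self, rng):
        dark = rng.uniform(0, 20, (8, 12))
        white = dark + rng.uniform(0.5, 100, (8, 12))
        ref = ReferenceSet(dark=dark, white=white)
        np.testing.assert_allclose(
            compute_reflectance(white[None], ref).values, 1.0, atol=1e-12
        )
        np.testing.assert_allclose(
            compute_reflectance(dark[None], ref).values, 0.0, atol=1e-12
        )

    def test_per_line_white_applied_line_by_line(self, rng):
        dark = np.zeros((4, 6))
        white = rng.uniform(10, 100, (3, 4, 6))
        ref = ReferenceSet(dark=dark, white=white)
        cube = compute_reflectance(white, ref)
        np.testing.assert_allclose(cube.values, 1.0)

    def test_invalid_denominator_masks_pixels(self):
        dark = np.full((2, 3), 5.0)
        white = dark.copy()
        white[0, 0] = 50.0  # only one valid pixel
        ref = ReferenceSet(dark=dark, white=white)
        cube = compute_reflectance(np.full((1, 2, 3), 20.0), ref)
        assert cube.mask[0, 0, 0]
        assert not cube.mask[0, 1, 1]

    def test_all_invalid_denominator_fails(self):
        dark = np.full((2, 3), 5.0)
        ref = ReferenceSet(dark=dark, white=dark.copy())
        with pytest.raises(BalancingError):
            compute_reflectance(np.zeros((1, 2, 3)), ref)

    def test_glare_clipped_to_cap(self):
        ref = self._ref(dark_level=0.0, white_level=10.0)
        cube = compute_reflectance(np.full((1, 6, 10), 1e5), ref, cap=4.0)
        np.testing.assert_allclose(cube.values, 4.0)


class TestAbsorbance:
    def _cube(self, value):
        ref = ReferenceSet(dark=np.zeros((2, 4)), white=np.ones((2, 4)))
        return compute_reflectance(np.full((1, 2, 4), value), ref)

    @pytest.mark.parametrize("refl,expected", [(1.0, 0.0), (0.01, 2.0)])
    def test_known_values(self, refl, expected):
        cube = compute_absorbance(self._cube(refl))
        np.testing.assert_allclose(cube.values, expected, atol=1e-12)

    def test_zero_reflectance_is_clipped_finite(self):
        cube = compute_absorbance(self._cube(0.0), floor=1e-4)
        np.testing.assert_allclose(cube.values, 4.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_absorbance_inverts_to_clipped_reflectance(self, seed):
        rng = np.random.default_rng(seed)
        refl_values = rng.uniform(0, 2, (2, 3, 5))
        ref = ReferenceSet(dark=np.zeros((3, 5)), white=np.ones((3, 5)))
        refl = compute_reflectance(refl_values, ref)
        floor = 1e-4
        absorb = compute_absorbance(refl, floor=floor)
        recovered = np.power(10.0, -absorb.values)
        np.testing.assert_allclose(
            recovered, np.maximum(refl.values, floor), rtol=1e-12
        )
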