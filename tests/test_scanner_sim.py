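"""Tests for the pushbroom forward model: scenes, illumination, sensor, scan."""

import numpy as np
import pytest

from pushbroom import scanner_sim as sim
from pushbroom.cube_pipeline import assemble_cube
from pushbroom.spectral_core import compute_reflectance

from conftest import make_small_config


class TestScenes:
    def test_usaf_scene_two_level_reflectance(self):
        scene = sim.make_usaf_scene([320.0])
        levels = {float(p.spectrum[0]) for p in scene.patches}
        assert levels == {0.05}
        assert float(scene.background[0]) == 0.9
        assert len(scene.elements) == 2  # both orientations
        widths = {el.width_um for el in scene.elements}
        assert widths == {320.0}

    def test_empty_width_list_gives_blank_scene(self):
        scene = sim.make_usaf_scene([])
        assert len(scene.patches) == 0
        np.testing.assert_allclose(scene.background, 0.9)

    def test_usaf_bar_pitch_matches_width(self):
        scene = sim.make_usaf_scene([320.0], orientations=("along",))
        bars = sorted(p.u0 for p in scene.patches)
        np.testing.assert_allclose(np.diff(bars), 2 * 0.320)

    def test_patch_reflectance_bounds_enforced(self):
        with pytest.raises(ValueError):
            sim.Patch(0, 1, 0, 1, np.full_like(sim.FINE_GRID_NM, 1.5))

    def test_tissue_absorbance_grows_with_amplitude(self):
        lo = sim.tissue_spectrum(0.1)
        hi = sim.tissue_spectrum(0.8)
        band = (sim.FINE_GRID_NM >= 530) & (sim.FINE_GRID_NM <= 590)
        nir = (sim.FINE_GRID_NM >= 785) & (sim.FINE_GRID_NM <= 825)
        assert hi[band].mean() < lo[band].mean()
        np.testing.assert_allclose(hi[nir], lo[nir])  # NIR untouched


class TestRadiance:
    def test_all_factors_unity_gives_flat_spectrum(self):
        cfg = make_small_config(
            light=sim.LightSourceModel(
                "flat", np.ones_like(sim.FINE_GRID_NM),
                half_intensity_radius_px=None, distance_exponent=0.0,
            ),
            psf_sigma_along_mm=0.0, psf_sigma_across_mm=0.0,
        )
        scene = sim.make_white_scene(1.0)
        center = sim.radiance_at(scene, cfg, cfg.n_lines // 2, cfg.sensor.n_spatial // 2)
        np.testing.assert_allclose(center, 1.0)

    def test_half_intensity_at_configured_radius(self):
        cfg = make_small_config(n_lines=640)
        scene = sim.make_white_scene(1.0)
        line_c = cfg.n_lines // 2
        sample_c = cfg.sensor.n_spatial // 2
        center = sim.radiance_at(scene, cfg, line_c, sample_c)
        r_half = cfg.light.half_intensity_radius_px
        off = sim.radiance_at(scene, cfg, int(line_c + r_half), sample_c)
        # radius differs from r_half by the half-pixel center offset only
        ratio = off / center
        assert np.allclose(ratio, 0.5, atol=0.01)

    def test_inverse_square_distance_scaling(self):
        base = make_small_config(
            light=sim.led_nir_source(),
        )
        cfg_near = sim.AcquisitionConfig(
            **{**base.__dict__, "light": sim.LightSourceModel(
                "led", base.light.spd, distance_exponent=2.0)}
        )
        cfg_far = sim.AcquisitionConfig(
            **{**cfg_near.__dict__, "distance_cm": 2 * cfg_near.distance_cm}
        )
        scene = sim.make_white_scene()
        near = sim.radiance_at(scene, cfg_near, 2, 5)
        # same pixel at doubled distance sees a different scene position, so
        # compare the distance factor on a flat scene where position is moot
        far = sim.radiance_at(scene, cfg_far, 2, 5)
        np.testing.assert_allclose(far / near, 0.25, rtol=1e-12)


class TestRenderAndScan:
    def test_noise_free_rendering_is_deterministic(self, small_config):
        scene = sim.make_colorchecker_scene()
        a = sim.render_raw_frame(scene, small_config, 3)
        b = sim.render_raw_frame(scene, small_config, 3)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_seeded_noise_is_bit_reproducible(self):
        cfg = make_small_config(read_noise_sigma=5.0, seed=42)
        scene = sim.make_white_scene()
        a = sim.render_raw_frame(scene, cfg, 7)
        b = sim.render_raw_frame(scene, cfg, 7)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_mean_of_noisy_frames_approaches_noise_free(self):
        sigma = 5.0
        cfg = make_small_config(read_noise_sigma=sigma, seed=3)
        clean_cfg = make_small_config(read_noise_sigma=0.0)
        scene = sim.make_white_scene()
        clean = sim.render_raw_frame(scene, clean_cfg, 5).intensities
        n = 400
        acc = np.zeros_like(clean)
        for i in range(n):
            rng = np.random.default_rng([3, 500 + i])
            acc += sim.render_raw_frame(scene, cfg, 5, rng=rng).intensities
        mean = acc / n
        z = (mean - clean) / (sigma / np.sqrt(n))
        # per-pixel z-scores: 99% within 3, all within 6 (law of large numbers)
        assert np.quantile(np.abs(z), 0.99) < 3.0
        assert np.abs(z).max() < 6.0

    def test_scan_emits_exactly_n_lines_in_order(self, small_config):
        stream, truth = sim.scan(sim.make_white_scene(), small_config)
        frames = list(stream)
        assert len(frames) == small_config.n_lines
        assert [f.line_index for f in frames] == list(range(small_config.n_lines))
        assert truth.shape == (
            small_config.n_lines, small_config.n_samples, small_config.n_channels
        )

    def test_single_line_scan(self):
        cfg = make_small_config(n_lines=1)
        stream, truth = sim.scan(sim.make_white_scene(), cfg)
        assert len(list(stream)) == 1
        assert truth.shape == (1, cfg.n_samples, 100)

    def test_two_scans_same_seed_identical(self):
        cfg = make_small_config(read_noise_sigma=4.0, seed=11, n_lines=5)
        scene = sim.make_colorchecker_scene()
        s1, _ = sim.scan(scene, cfg)
        s2, _ = sim.scan(scene, cfg)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.intensities, b.intensities)


class TestReferences:
    def test_noise_free_dark_equals_black_level(self, small_config):
        ref = sim.acquire_references(small_config, n_dark=3)
        np.testing.assert_allclose(ref.dark, small_config.sensor.black_level)

    def test_white_ratio_follows_inverse_square(self):
        light = sim.LightSourceModel(
            "led", sim.led_nir_source().spd, half_intensity_radius_px=None,
            distance_exponent=2.0,
        )
        near = make_small_config(light=light, n_lines=4)
        far = make_small_config(light=light, n_lines=4, distance_cm=10.0)
        ref_near = sim.acquire_references(near, n_dark=2)
        ref_far = sim.acquire_references(far, n_dark=2)
        signal_near = ref_near.white_frame - ref_near.dark
        signal_far = ref_far.white_frame - ref_far.dark
        ratio = signal_near / signal_far
        np.testing.assert_allclose(ratio, 4.0, rtol=1e-6)

    def test_validity_mask_all_true_for_default_white(self, small_config):
        ref = sim.acquire_references(small_config, n_dark=2)
        assert ref.validity_mask().all()


class TestEndToEnd:
    def test_white_scan_balances_to_unity(self, small_config):
        # Includes the sensor QE ripple above 800 nm, which must cancel in
        # the white balancing.
        scene = sim.make_white_scene()
        ref = sim.acquire_references(small_config, n_dark=2)
        stream, _ = sim.scan(scene, small_config)
        cube = assemble_cube(stream, small_config.calibration, ref)
        assert np.abs(cube.values[cube.mask] - 1.0).max() <= 1e-6

    def test_qe_ripple_cancels_exactly_for_unit_scene(self, small_config):
        scene = sim.make_white_scene(1.0)
        ref = sim.acquire_references(small_config, n_dark=2, white_scene=scene)
        stream, _ = sim.scan(scene, small_config)
        cube = assemble_cube(stream, small_config.calibration, ref)
        assert np.abs(cube.values[cube.mask] - 1.0).max() <= 1e-10

    def test_colorchecker_ground_truth_recovery(self):
        # Noise-free scan; per-patch interior spectra must match the scene's
        # ground-truth reflectance closely once balanced against a unit
        # white reference.
        cfg = make_small_config(n_lines=48, distance_cm=7.0, seed=2)
        scene = sim.make_colorchecker_scene(patch_mm=10.0, gap_mm=2.0)
        ref = sim.acquire_references(cfg, white_scene=sim.make_white_scene(1.0))
        stream, truth = sim.scan(scene, cfg)
        cube = assemble_cube(stream, cfg.calibration, ref)
        u = cfg.line_u_mm(np.arange(cfg.n_lines))
        v = cfg.binned_sample_v_mm(np.arange(cfg.n_samples))
        margin = 2.5
        checked = 0
        for patch in scene.patches:
            iu = np.flatnonzero((u >= patch.u0 + margin) & (u <= patch.u1 - margin))
            iv = np.flatnonzero((v >= patch.v0 + margin) & (v <= patch.v1 - margin))
            if not (iu.size and iv.size):
                continue
            measured = cube.values[np.ix_(iu, iv)].mean(axis=(0, 1))
            expected = truth.values[iu[0], iv[0]]
            rmse = np.sqrt(np.mean((measured - expected) ** 2))
            assert rmse <= 0.005, f"patch {patch.name}: RMSE {rmse:.4f}"
            checked += 1
        assert checked >= 8

    def test_vignetting_monotone_with_radius(self):
        # Dark-subtracted white intensity must not increase with radius from
        # the spot center.
        cfg = make_small_config(n_lines=64)
        ref = sim.acquire_references(cfg, n_dark=2)
        signal = ref.white - ref.dark  # (lines, samples, channels)
        mid_channel = 40
        img = signal[..., mid_channel]
        center = (cfg.n_lines / 2 - 0.5, cfg.n_samples / 2 - 0.5)
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        # convert sample index to output-pixel units used by the spot model
        radius = np.hypot(yy - center[0], xx - center[1])
        order = np.argsort(radius.ravel())
        values = img.ravel()[order]
        # azimuthal scatter exists because the FOV is anisotropic; compare
        # smoothed bins rather than raw neighbors
        bins = np.array_split(values, 16)
        means = np.array([b.mean() for b in bins])
        assert np.all(np.diff(means) <= 1e-9)
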