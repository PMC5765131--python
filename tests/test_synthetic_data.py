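import math

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from binoica import synthetic_data as sd

ARC = 60.0 * 180.0 / math.pi


class TestDepthToDisparity:
    def test_fixated_point_zero(self, geometry):
        assert sd.depth_to_horizontal_disparity(geometry.fixation_mm,
                                                geometry) == pytest.approx(0.0)

    def test_far_point_positive(self):
        # independent evaluation: 65 * (1/1000 - 1/2000) rad -> arcmin
        expected = 65.0 * (1.0 / 1000.0 - 1.0 / 2000.0) * ARC
        geom = sd.ViewingGeometry(65.0, 1000.0, 600.0, 1.0)
        got = sd.depth_to_horizontal_disparity(2000.0, geom)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(111.7268, abs=1e-3)
        assert got > 0

    def test_near_point_sign_flip(self):
        geom = sd.ViewingGeometry(65.0, 2000.0, 600.0, 1.0)
        got = sd.depth_to_horizontal_disparity(1000.0, geom)
        assert got == pytest.approx(-111.7268, abs=1e-3)

    def test_monotone_decreasing_in_depth(self, geometry):
        depths = np.linspace(200.0, 5000.0, 200)
        d = sd.depth_to_horizontal_disparity(depths, geometry)
        assert np.all(np.diff(d) > 0)  # disparity grows with Z => far positive
        # strictly monotone *decreasing* as a function of nearness 1/Z
        assert np.all(np.diff(sd.depth_to_horizontal_disparity(
            1.0 / np.linspace(1e-4, 1e-3, 50), geometry)) < 0)

    def test_nonpositive_depth_rejected(self, geometry):
        with pytest.raises(ValueError):
            sd.depth_to_horizontal_disparity(0.0, geometry)
        with pytest.raises(ValueError):
            sd.depth_to_horizontal_disparity(np.array([100.0, -5.0]), geometry)


class TestVerticalField:
    def test_zero_gain(self):
        az, el = np.meshgrid(np.linspace(-100, 100, 7), np.linspace(-100, 100, 7))
        assert np.all(sd.vertical_disparity_field(az, el, 0.0) == 0.0)

    def test_quadrant_signs(self):
        assert sd.vertical_disparity_field(-100.0, 100.0, 1e-4) == pytest.approx(1.0)
        assert sd.vertical_disparity_field(100.0, 100.0, 1e-4) == pytest.approx(-1.0)
        assert sd.vertical_disparity_field(100.0, -100.0, 1e-4) > 0  # bottom-right
        assert sd.vertical_disparity_field(-100.0, -100.0, 1e-4) < 0  # bottom-left

    def test_zero_on_horizontal_meridian(self):
        az = np.linspace(-500, 500, 11)
        assert np.all(sd.vertical_disparity_field(az, np.zeros_like(az), 1e-3) == 0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        az = rng.uniform(-500, 500, 100)
        el = rng.uniform(-500, 500, 100)
        v = sd.vertical_disparity_field(az, el, 3e-5)
        np.testing.assert_allclose(sd.vertical_disparity_field(-az, el, 3e-5), -v)
        np.testing.assert_allclose(sd.vertical_disparity_field(az, -el, 3e-5), -v)

    def test_grows_away_from_meridians(self):
        v1 = abs(sd.vertical_disparity_field(100.0, 50.0, 1e-4))
        v2 = abs(sd.vertical_disparity_field(200.0, 50.0, 1e-4))
        v3 = abs(sd.vertical_disparity_field(100.0, 150.0, 1e-4))
        assert v2 > v1 and v3 > v1


class TestRenderStereoPair:
    def test_flat_depth_zero_gain_identical_eyes(self, geometry):
        depth = np.full((geometry.raster_size,) * 2, geometry.fixation_mm)
        scene = sd.SceneSpec(depth_map=depth, vertical_gain=0.0, rng_seed=1)
        pair, truth = sd.render_stereo_pair(scene, geometry)
        np.testing.assert_array_equal(pair.left, pair.right)
        assert np.all(truth.horizontal == 0)

    def test_uniform_shift_cross_correlation(self, geometry):
        d0 = 8.0
        depth = sd.uniform_disparity_depth(d0, geometry, (geometry.raster_size,) * 2)
        scene = sd.SceneSpec(depth_map=depth, rng_seed=2)
        pair, truth = sd.render_stereo_pair(scene, geometry)
        assert np.allclose(truth.horizontal, d0, atol=1e-9)
        # brute-force cross-correlation oracle on an interior window
        win = np.s_[150:250, 150:250]
        target = pair.right[win]
        shifts = np.arange(-12, 13)
        corr = [np.sum(np.roll(pair.left, s, axis=1)[win] * target)
                for s in shifts]
        # right(x) = left(x - d0/pitch): best match rolls left right by +8 px
        assert shifts[int(np.argmax(corr))] == int(d0 / geometry.pixel_pitch_arcmin)

    def test_ground_plane_disparity_sign_gradient(self):
        geom = sd.ViewingGeometry(65.0, 10_000.0, 200.0)
        scene = sd.SceneSpec(eye_height_mm=1600.0, rng_seed=3)
        _, truth = sd.render_stereo_pair(scene, geom)
        n = truth.horizontal.shape[0]
        assert np.median(truth.horizontal[: n // 4]) > 0  # top rows: far
        assert np.median(truth.horizontal[-n // 4:]) < 0  # bottom rows: near

    def test_vertical_disparity_feature_higher_in_left(self, geometry):
        # uniform positive v imposed via a gain and single-quadrant check
        scene = sd.SceneSpec(
            depth_map=np.full((geometry.raster_size,) * 2, geometry.fixation_mm),
            vertical_gain=5e-5, rng_seed=4)
        pair, truth = sd.render_stereo_pair(scene, geometry)
        r, c = 100, 100  # top-left quadrant: v > 0 there
        assert truth.vertical[r, c] > 0
        # feature higher in left: left at (r, c) equals texture lower down,
        # so right row r + v matches left row r
        shift_px = truth.vertical[r, c] / geometry.pixel_pitch_arcmin
        win = np.s_[90:110, 90:110]
        target = pair.left[win]
        shifts = np.arange(-6, 7)
        corr = [np.sum(np.roll(pair.right, -s, axis=0)[win] * target)
                for s in shifts]
        assert shifts[int(np.argmax(corr))] == pytest.approx(round(shift_px), abs=1)

    def test_warp_round_trip(self):
        geom = sd.ViewingGeometry(65.0, 10_000.0, 150.0)
        scene = sd.SceneSpec(eye_height_mm=1600.0, vertical_gain=2e-5,
                             texture_cutoff=0.05, rng_seed=5)
        pair, truth = sd.render_stereo_pair(scene, geom)
        rng = np.random.default_rng(5)  # same stream the renderer used
        texture = sd.synth_texture(pair.left.shape, scene.texture_alpha, rng,
                                   cutoff=0.05)
        n = pair.left.shape[0]
        rows, cols = np.meshgrid(np.arange(n, dtype=float),
                                 np.arange(n, dtype=float), indexing="ij")
        dr = truth.vertical / 2.0
        dc = truth.horizontal / 2.0
        recovered = map_coordinates(pair.left, [rows - dr, cols - dc],
                                    order=1, mode="grid-wrap")
        err = np.sqrt(np.mean((recovered - texture) ** 2)) / texture.std()
        assert err < 0.02

    def test_deterministic_given_seed(self, geometry):
        scene = sd.SceneSpec(eye_height_mm=900.0, rng_seed=7)
        geom = sd.ViewingGeometry(65.0, 10_000.0, 100.0)
        a, _ = sd.render_stereo_pair(scene, geom)
        b, _ = sd.render_stereo_pair(scene, geom)
        np.testing.assert_array_equal(a.left, b.left)
        np.testing.assert_array_equal(a.right, b.right)

    def test_warp_budget_enforced(self, geometry):
        depth = sd.uniform_disparity_depth(50.0, geometry,
                                           (geometry.raster_size,) * 2)
        scene = sd.SceneSpec(depth_map=depth, rng_seed=1)
        with pytest.raises(ValueError, match="budget"):
            sd.render_stereo_pair(scene, geometry, max_warp_arcmin=10.0)


class TestTexture:
    def test_unit_variance_zero_mean(self):
        tex = sd.synth_texture((256, 256), 1.0, np.random.default_rng(0))
        assert tex.mean() == pytest.approx(0.0, abs=1e-12)
        assert tex.std() == pytest.approx(1.0)

    def test_power_spectrum_decreasing(self):
        tex = sd.synth_texture((512, 512), 1.0, np.random.default_rng(1))
        power = np.abs(np.fft.fft2(tex)) ** 2
        f = np.hypot(np.fft.fftfreq(512)[:, None], np.fft.fftfreq(512)[None, :])
        low = power[(f > 0.01) & (f < 0.05)].mean()
        mid = power[(f > 0.08) & (f < 0.15)].mean()
        high = power[(f > 0.3)].mean()
        assert low > mid > high

    def test_heavy_tails(self):
        from scipy.stats import kurtosis
        tex = sd.synth_texture((512, 512), 1.0, np.random.default_rng(2))
        assert kurtosis(tex.ravel()) > 1.0  # sparse structure, not Gaussian


class TestGaborPatchFixture:
    def test_centre_values(self):
        from binoica.gabor import GaborParams
        p = GaborParams(theta=0.3, f=0.1, phi=0.0, sigma_w=3, sigma_h=3, psi=0.0)
        patch = sd.make_gabor_patch(p, 16)
        assert patch[8, 8] == pytest.approx(1.0)  # envelope 1 x cos 0
        p90 = GaborParams(theta=0.3, f=0.1, phi=math.pi / 2, sigma_w=3,
                          sigma_h=3, psi=0.0)
        assert sd.make_gabor_patch(p90, 16)[8, 8] == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_evaluation(self):
        # second, independent implementation of the Gabor surface
        from binoica.gabor import GaborParams
        p = GaborParams(theta=0.7, f=0.2, phi=1.1, sigma_w=2.5, sigma_h=3.5,
                        psi=0.4, centre_x=1.0, centre_y=-0.5, amplitude=1.3)
        patch = sd.make_gabor_patch(p, 12, noise_sd=0.0)
        n = 12
        for row in range(n):
            for col in range(n):
                x = col - n // 2 - p.centre_x
                y = (n // 2 - row) - p.centre_y
                xr = x * math.cos(p.psi) - y * math.sin(p.psi)
                yr = x * math.sin(p.psi) + y * math.cos(p.psi)
                z = x * math.cos(p.theta) - y * math.sin(p.theta)
                val = p.amplitude * math.exp(
                    -xr ** 2 / (2 * p.sigma_w ** 2)
                    - yr ** 2 / (2 * p.sigma_h ** 2)
                ) * math.cos(2 * math.pi * p.f * z + p.phi)
                assert patch[row, col] == pytest.approx(val, abs=1e-12)

    def test_nyquist_rejected(self):
        from binoica.gabor import GaborParams
        p = GaborParams(theta=0.0, f=0.5, phi=0.0, sigma_w=3, sigma_h=3, psi=0.0)
        with pytest.raises(ValueError, match="Nyquist"):
            sd.make_gabor_patch(p, 16)

    def test_noise_deterministic(self):
        from binoica.gabor import GaborParams
        p = GaborParams(theta=0.3, f=0.1, phi=0.0, sigma_w=3, sigma_h=3, psi=0.0)
        a = sd.make_gabor_patch(p, 16, noise_sd=0.3, rng_seed=9)
        b = sd.make_gabor_patch(p, 16, noise_sd=0.3, rng_seed=9)
        np.testing.assert_array_equal(a, b)


class TestSparseSources:
    def test_identity_mixing_returns_sources(self):
        data_id, mix_id = sd.make_sparse_source_patches(
            5, 1000, source_seed=3, identity_mixing=True)
        np.testing.assert_array_equal(mix_id, np.eye(5))
        data, mix = sd.make_sparse_source_patches(5, 1000, mixing_seed=1,
                                                  source_seed=3)
        np.testing.assert_allclose(np.linalg.solve(mix, data), data_id,
                                   atol=1e-10)

    def test_full_rank(self):
        for seed in range(5):
            _, mix = sd.make_sparse_source_patches(8, 500, mixing_seed=seed)
            assert np.linalg.matrix_rank(mix) == 8

    def test_deterministic(self):
        a, ma = sd.make_sparse_source_patches(6, 400, 11, 12)
        b, mb = sd.make_sparse_source_patches(6, 400, 11, 12)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(ma, mb)

    def test_needs_more_samples_than_sources(self):
        with pytest.raises(ValueError):
            sd.make_sparse_source_patches(10, 10)
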