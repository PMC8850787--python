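"""Density maps, local count maps and pseudo foreground masks from dots."""

import numpy as np
import pytest

from badacount.targets import (
    DotAnnotationSet,
    DensityMap,
    default_threshold,
    downsample_mask,
    gaussian_peak,
    make_density_map,
    make_foreground_mask,
    make_local_count_map,
)

from conftest import brute_force_block_sums, brute_force_density, brute_force_mask


class TestDensityMap:
    def test_no_dots_gives_zero_map(self):
        dots = DotAnnotationSet("empty", np.empty((0, 2)), (64, 64))
        dm = make_density_map(dots, sigma=4.0)
        assert dm.values.shape == (64, 64)
        assert dm.total == 0.0

    def test_single_interior_dot_integrates_to_one(self, single_dot_64):
        dm = make_density_map(single_dot_64, sigma=4.0)
        assert 0.999 <= dm.total <= 1.001
        assert np.unravel_index(dm.values.argmax(), dm.values.shape) == (32, 32)

    def test_coincident_dots_double_the_map(self, single_dot_64):
        one = make_density_map(single_dot_64, sigma=4.0)
        two = make_density_map(
            DotAnnotationSet("two", [(32.0, 32.0), (32.0, 32.0)], (64, 64)), sigma=4.0
        )
        np.testing.assert_array_equal(two.values, 2.0 * one.values)

    def test_linearity_over_dot_set_union(self, rng):
        pts = rng.uniform(0, 48, size=(6, 2))
        a = make_density_map(DotAnnotationSet("a", pts[:3], (48, 48)), 3.0)
        b = make_density_map(DotAnnotationSet("b", pts[3:], (48, 48)), 3.0)
        ab = make_density_map(DotAnnotationSet("ab", pts, (48, 48)), 3.0)
        np.testing.assert_allclose(ab.values, a.values + b.values, atol=1e-12)

    @pytest.mark.parametrize("sigma", [1.5, 4.0, 8.0])
    def test_matches_brute_force_including_borders(self, rng, sigma):
        # dots near borders exercise kernel truncation
        pts = np.concatenate(
            [rng.uniform(0, 60, size=(3, 2)), [[0.5, 1.0], [59.0, 58.5]]]
        )
        dots = DotAnnotationSet("bf", pts, (60, 60))
        dm = make_density_map(dots, sigma)
        np.testing.assert_allclose(
            dm.values, brute_force_density(pts, 60, 60, sigma), atol=1e-9
        )

    def test_interior_dots_conserve_count(self, rng):
        # all dots >= 4 sigma from every border
        sigma = 3.0
        pts = rng.uniform(16, 112, size=(5, 2))
        dm = make_density_map(DotAnnotationSet("c", pts, (128, 128)), sigma)
        assert abs(dm.total - 5) <= 1e-3 * 5

    def test_out_of_bounds_dot_names_image_and_index(self):
        with pytest.raises(ValueError, match=r"bad_img.*point 1"):
            DotAnnotationSet("bad_img", [(3.0, 3.0), (70.0, 2.0)], (64, 64))

    def test_nonpositive_sigma_rejected(self, single_dot_64):
        with pytest.raises(ValueError):
            make_density_map(single_dot_64, sigma=0.0)


class TestLocalCountMap:
    def test_uniform_density_box_sums(self):
        dm = DensityMap(np.full((128, 128), 1.0 / 4096), 4.0)
        lcm = make_local_count_map(dm, 64, 64)
        np.testing.assert_allclose(lcm.values, np.ones((2, 2)), rtol=1e-12)

    def test_output_resolution_is_one_sixty_fourth(self):
        lcm = make_local_count_map(DensityMap(np.zeros((512, 512)), 4.0), 64, 64)
        assert lcm.values.shape == (8, 8)

    def test_dot_centered_in_block_concentrates_count(self):
        dots = DotAnnotationSet("c", [(96.0, 32.0)], (64, 128))  # block (0, 1)
        lcm = make_local_count_map(make_density_map(dots, 4.0), 64, 64)
        assert lcm.values[0, 1] >= 0.999
        assert lcm.values[0, 0] <= 1e-3

    def test_matches_brute_force_block_sums(self, rng):
        vals = rng.random((48, 64))
        lcm = make_local_count_map(DensityMap(vals, 1.0), 16, 16)
        np.testing.assert_allclose(
            lcm.values, brute_force_block_sums(vals, 16, 16), atol=1e-9
        )

    def test_count_conservation_for_divisible_sizes(self, rng):
        dots = DotAnnotationSet("c", rng.uniform(0, 128, size=(7, 2)), (128, 128))
        dm = make_density_map(dots, 4.0)
        lcm = make_local_count_map(dm, 64, 64)
        assert abs(lcm.total - dm.total) <= 1e-6 * max(dm.total, 1.0)

    def test_partial_blocks_dropped_with_warning(self):
        dm = DensityMap(np.ones((70, 70)), 1.0)
        with pytest.warns(UserWarning, match="partial blocks"):
            lcm = make_local_count_map(dm, 64, 64)
        assert lcm.values.shape == (1, 1)
        assert lcm.values[0, 0] == pytest.approx(64 * 64)

    def test_patch_larger_than_map_rejected(self):
        with pytest.raises(ValueError):
            make_local_count_map(DensityMap(np.zeros((32, 32)), 1.0), 64, 64)


class TestForegroundMask:
    def test_zero_threshold_marks_everything(self, single_dot_64):
        dm = make_density_map(single_dot_64, 4.0)
        assert make_foreground_mask(dm, 0.0).values.all()

    def test_threshold_above_max_marks_nothing(self, single_dot_64):
        dm = make_density_map(single_dot_64, 4.0)
        assert not make_foreground_mask(dm, dm.values.max() * 1.01).values.any()

    def test_isocontour_is_a_disk_of_predicted_radius(self):
        # threshold at 5% of the kernel peak -> disk radius sqrt(2 sigma^2 ln 20)
        sigma = 8.0
        dots = DotAnnotationSet("d", [(32.0, 32.0)], (64, 64))
        dm = make_density_map(dots, sigma)
        mask = make_foreground_mask(dm, default_threshold(sigma))
        r_pred = np.sqrt(2 * sigma**2 * np.log(20.0))
        assert r_pred == pytest.approx(19.56, abs=0.05)
        yy, xx = np.mgrid[0:64, 0:64]
        dist = np.hypot(xx - 32.0, yy - 32.0)
        assert mask.values[dist <= r_pred - 1.0].all()
        assert not mask.values[dist >= r_pred + 1.0].any()

    def test_matches_brute_force_thresholding(self, rng):
        dots = DotAnnotationSet("bf", rng.uniform(0, 40, (4, 2)), (40, 40))
        dm = make_density_map(dots, 3.0)
        t = default_threshold(3.0)
        np.testing.assert_array_equal(
            make_foreground_mask(dm, t).values, brute_force_mask(dm.values, t)
        )

    def test_monotone_in_threshold(self, rng):
        dots = DotAnnotationSet("m", rng.uniform(0, 64, (5, 2)), (64, 64))
        dm = make_density_map(dots, 4.0)
        peak = gaussian_peak(4.0)
        prev = make_foreground_mask(dm, 0.0).values
        for frac in (0.01, 0.05, 0.2, 0.8):
            cur = make_foreground_mask(dm, frac * peak).values
            assert (cur <= prev).all()  # raising t_c never adds foreground
            prev = cur


class TestDownsampleMask:
    def _mask(self, values):
        from badacount.targets import ForegroundMask

        return ForegroundMask(np.asarray(values, dtype=np.uint8))

    def test_zero_mask_stays_zero(self):
        out = downsample_mask(self._mask(np.zeros((32, 32))), 8)
        assert out.values.shape == (4, 4) and not out.values.any()

    def test_single_pixel_survives(self):
        v = np.zeros((32, 32))
        v[17, 5] = 1
        out = downsample_mask(self._mask(v), 8)
        assert out.values.sum() == 1 and out.values[2, 0] == 1

    def test_disk_matches_blockwise_any(self):
        yy, xx = np.mgrid[0:64, 0:64]
        v = (np.hypot(xx - 32, yy - 32) <= 19.6).astype(np.uint8)
        out = downsample_mask(self._mask(v), 8)
        expected = v.reshape(8, 8, 8, 8).max(axis=(1, 3))
        np.testing.assert_array_equal(out.values, expected)

    def test_downsampled_masks_nest_as_threshold_grows(self, rng):
        dots = DotAnnotationSet("n", rng.uniform(0, 64, (5, 2)), (64, 64))
        dm = make_density_map(dots, 4.0)
        lo = downsample_mask(make_foreground_mask(dm, default_threshold(4.0)), 8)
        hi = downsample_mask(make_foreground_mask(dm, 4 * default_threshold(4.0)), 8)
        assert (hi.values <= lo.values).all()

    def test_non_divisible_factor_warns(self):
        with pytest.warns(UserWarning):
            out = downsample_mask(self._mask(np.ones((30, 30))), 8)
        assert out.values.shape == (3, 3)
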