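"""Grayscale filters and binary morphology against direct oracles."""

import numpy as np
import pytest

from colonyedge import image_ops as ops
from colonyedge.core import BinaryMask, Raster

from conftest import disk_mask, random_mask, random_raster
from oracles import (
    close_naive,
    conv2d_replicate,
    fill_holes_naive,
    grey_opening_ball_naive,
    quantile_rescale_naive,
    rank_filter_naive,
    remove_outliers_naive,
)


class TestToGrayscale:
    def test_grayscale_passthrough(self):
        arr = np.arange(12.0).reshape(3, 4)
        out = ops.to_grayscale(arr, "red")
        np.testing.assert_array_equal(out.pixels, arr)

    def test_channel_extraction(self):
        rgb = np.zeros((2, 2, 3))
        rgb[:, :, 0] = 7.0
        rgb[:, :, 2] = [[9.0, 1.0], [2.0, 3.0]]
        np.testing.assert_array_equal(ops.to_grayscale(rgb, "red").pixels, 7.0)
        np.testing.assert_array_equal(
            ops.to_grayscale(rgb, "blue").pixels, rgb[:, :, 2]
        )

    def test_luminance_weights_sum_to_one(self):
        rgb = np.full((2, 2, 3), 13.0)
        np.testing.assert_allclose(ops.to_grayscale(rgb, "luminance").pixels, 13.0)

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            ops.to_grayscale(np.zeros((2, 2, 3)), "alpha")


class TestSubtractBackground:
    def test_constant_raster_goes_to_zero(self):
        out = ops.subtract_background(Raster(np.full((16, 16), 80.0)), radius=4)
        np.testing.assert_allclose(out.pixels, 0.0)

    def test_bright_disk_preserved_on_flat_background(self):
        img = np.full((50, 50), 50.0)
        img[disk_mask(50, 50, 25, 25, 5)] += 100.0
        out = ops.subtract_background(Raster(img), radius=20, shrink=1)
        assert abs(out.pixels[25, 25] - 100.0) <= 5.0
        assert out.pixels[5, 5] == pytest.approx(0.0, abs=1e-9)

    def test_gradient_removed_under_large_ball(self):
        yy, xx = np.mgrid[0:40, 0:40]
        img = 40.0 + 0.2 * xx + 0.1 * yy
        obj = disk_mask(40, 40, 20, 20, 4)
        img[obj] += 60.0
        out = ops.subtract_background(Raster(img), radius=15, shrink=1)
        assert np.max(out.pixels[~obj]) < 0.1 * 60.0

    def test_matches_ball_opening_oracle(self, rng):
        for _ in range(5):
            r = random_raster(rng, max_side=18)
            radius = int(rng.integers(2, 5))
            bg = grey_opening_ball_naive(r.pixels, radius)
            bg = np.minimum(bg, r.pixels)
            got = ops.subtract_background(r, radius, shrink=1)
            np.testing.assert_allclose(got.pixels, np.clip(r.pixels - bg, 0, None), atol=1e-9)

    def test_light_background_polarity(self):
        img = np.full((20, 20), 200.0)
        img[disk_mask(20, 20, 10, 10, 3)] -= 120.0  # dark object
        out = ops.subtract_background(Raster(img), radius=8, light_background=True, shrink=1)
        # background pushed to white, object stays dark relative to it
        assert out.pixels[1, 1] == pytest.approx(255.0)
        assert out.pixels[10, 10] < 150.0

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            ops.subtract_background(Raster(np.zeros((4, 4))), radius=0)


class TestSharpen:
    def test_constant_unchanged(self):
        out = ops.sharpen(Raster(np.full((8, 8), 42.0)))
        np.testing.assert_allclose(out.pixels, 42.0)

    def test_impulse_response(self):
        img = np.zeros((9, 9))
        img[4, 4] = 4.0
        out = ops.sharpen(Raster(img))
        assert out.pixels[4, 4] == pytest.approx(12.0)
        # negative lobes clip to zero at the output depth
        assert out.pixels[4, 5] == pytest.approx(0.0)
        unclipped = conv2d_replicate(img, ops._SHARPEN_KERNEL)
        assert unclipped[4, 5] == pytest.approx(-1.0)

    def test_step_edge_overshoot(self):
        img = np.zeros((8, 8))
        img[:, 4:] = 100.0
        out = ops.sharpen(Raster(img))
        assert out.pixels[4, 4] > 100.0  # bright-side overshoot
        assert out.pixels[4, 3] == 0.0   # dark-side undershoot clipped

    def test_matches_convolution_oracle_within_range(self, rng):
        for _ in range(10):
            r = random_raster(rng)
            want = np.clip(conv2d_replicate(r.pixels, ops._SHARPEN_KERNEL), 0, 255)
            np.testing.assert_allclose(ops.sharpen(r).pixels, want, atol=1e-9)


class TestEnhanceContrast:
    def test_full_range_unchanged_at_zero_fraction(self):
        img = np.linspace(0, 255, 64).reshape(8, 8)
        out = ops.enhance_contrast(Raster(img), 0.0)
        np.testing.assert_allclose(out.pixels, img, atol=1e-9)

    def test_two_values_map_to_endpoints(self):
        img = np.array([[10.0, 200.0]] * 4)
        out = ops.enhance_contrast(Raster(img), 0.0)
        assert set(np.unique(out.pixels)) == {0.0, 255.0}

    def test_outliers_saturated(self, rng):
        img = rng.uniform(100, 150, size=(25, 40))
        img[0, 0] = 0.0
        img[0, 1] = 255.0
        out = ops.enhance_contrast(Raster(img), 0.004)
        assert out.pixels[0, 0] == 0.0
        assert out.pixels[0, 1] == 255.0
        inner = out.pixels[1:]
        assert inner.max() - inner.min() > 200.0  # stretched to most of the range

    def test_matches_quantile_oracle(self, rng):
        for _ in range(10):
            r = random_raster(rng)
            frac = float(rng.uniform(0, 0.2))
            want = quantile_rescale_naive(r.pixels, frac, 255.0)
            np.testing.assert_allclose(
                ops.enhance_contrast(r, frac).pixels, want, atol=1e-6
            )

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ops.enhance_contrast(Raster(np.zeros((3, 3))), 0.5)


class TestSobel:
    def test_constant_gives_zero(self):
        out = ops.sobel_edges(Raster(np.full((6, 6), 9.0)))
        np.testing.assert_allclose(out.pixels, 0.0)

    def test_vertical_step_response(self):
        h = 30.0
        img = np.zeros((9, 9))
        img[:, 5:] = h
        out = ops.sobel_edges(Raster(img))
        assert out.pixels[4, 4] == pytest.approx(4 * h)
        assert out.pixels[4, 5] == pytest.approx(4 * h)

    def test_rotation_symmetry(self, rng):
        r = random_raster(rng)
        rot = Raster(np.rot90(r.pixels).copy())
        np.testing.assert_allclose(
            ops.sobel_edges(rot).pixels, np.rot90(ops.sobel_edges(r).pixels), atol=1e-9
        )

    def test_matches_convolution_oracle(self, rng):
        for _ in range(10):
            r = random_raster(rng)
            gx = conv2d_replicate(r.pixels, ops._SOBEL_X)
            gy = conv2d_replicate(r.pixels, ops._SOBEL_Y)
            np.testing.assert_allclose(
                ops.sobel_edges(r).pixels, np.hypot(gx, gy), atol=1e-9
            )


class TestGaussianBlur:
    def test_constant_unchanged(self):
        out = ops.gaussian_blur(Raster(np.full((7, 7), 3.0)), 1.5)
        np.testing.assert_allclose(out.pixels, 3.0)

    def test_impulse_normalised(self):
        img = np.zeros((31, 31))
        img[15, 15] = 1.0
        out = ops.gaussian_blur(Raster(img), 2.0)
        assert out.pixels.sum() == pytest.approx(1.0, abs=1e-6)
        assert out.pixels.argmax() == 15 * 31 + 15

    def test_impulse_matches_dense_kernel(self):
        sigma = 2.0
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = ops.gaussian_blur(Raster(img), sigma)
        radius = int(3.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-(x**2) / (2 * sigma**2))
        k1 /= k1.sum()
        dense = np.outer(k1, k1)
        np.testing.assert_allclose(
            out.pixels[20 - radius : 20 + radius + 1, 20 - radius : 20 + radius + 1],
            dense,
            atol=1e-12,
        )

    def test_binary_mask_smoothing(self):
        # a 1-px speck melts away, a solid block survives
        m = np.zeros((20, 20), dtype=bool)
        m[3, 3] = True
        m[8:16, 8:16] = True
        out = ops.gaussian_blur(BinaryMask(m), 2.0)
        assert not out.pixels[3, 3]
        assert out.pixels[11, 11]

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError):
            ops.gaussian_blur(Raster(np.zeros((3, 3))), 0.0)


class TestMakeBinary:
    def test_constant_is_all_background(self):
        out = ops.make_binary(Raster(np.full((5, 5), 7.0)))
        assert not out.pixels.any()

    def test_bimodal_split_at_intermeans_fixpoint(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 200.0
        img[:, :5] = 10.0
        assert ops.isodata_threshold(img) == pytest.approx(105.0)
        out = ops.make_binary(Raster(img))
        np.testing.assert_array_equal(out.pixels, img > 105)

    def test_partitions_all_pixels(self, rng):
        r = random_raster(rng)
        out = ops.make_binary(r)
        assert out.pixels.shape == r.shape
        assert out.pixels.dtype == bool

    def test_threshold_is_intermeans_fixpoint(self, rng):
        for _ in range(20):
            vals = rng.integers(0, 256, size=int(rng.integers(10, 400))).astype(float)
            if vals.min() == vals.max():
                continue
            t = ops.isodata_threshold(vals)
            below, above = vals[vals <= t], vals[vals > t]
            if below.size and above.size:
                assert t == pytest.approx((below.mean() + above.mean()) / 2, abs=1e-6)

    def test_agrees_with_skimage_on_integer_data(self, rng):
        from skimage.filters import threshold_isodata

        for _ in range(10):
            vals = rng.integers(0, 40, size=(16, 16)).astype(float)
            if vals.min() == vals.max():
                continue
            t_ours = ops.isodata_threshold(vals)
            t_sk = float(threshold_isodata(vals.astype(int)))
            # intermeans can admit several fixpoints and skimage snaps to
            # integer bins, so compare the resulting classifications:
            # they may disagree on at most a few bins' worth of pixels
            disagree = np.mean((vals > t_ours) != (vals > t_sk))
            assert disagree <= 0.08

    def test_idempotent_on_its_own_output(self, rng):
        m = random_mask(rng)
        as_image = Raster(np.where(m.pixels, 255.0, 0.0))
        again = ops.make_binary(as_image)
        np.testing.assert_array_equal(again.pixels, m.pixels)


class TestBinaryMorphology:
    def test_close_keeps_solid_disk(self):
        m = BinaryMask(disk_mask(21, 21, 10, 10, 6))
        out = ops.morphological_close(m)
        np.testing.assert_array_equal(out.pixels, m.pixels)

    def test_close_bridges_one_pixel_gap_in_outline(self):
        # one-pixel-thick circle outline with a cut: after closing the
        # loop is sealed again, so the interior becomes a fillable hole
        yy, xx = np.mgrid[0:25, 0:25]
        d = np.hypot(yy - 12, xx - 12)
        ring = np.abs(d - 8) <= 0.5
        ring[12, 20] = False
        broken = ops.fill_holes(BinaryMask(ring))
        assert not broken.pixels[12, 12]  # gap lets the flood in
        closed = ops.morphological_close(BinaryMask(ring))
        np.testing.assert_array_equal(closed.pixels, close_naive(ring, 1))
        sealed = ops.fill_holes(closed)
        assert sealed.pixels[12, 12]

    def test_close_is_extensive_and_matches_oracle(self, rng):
        for _ in range(8):
            m = random_mask(rng, max_side=16)
            it = int(rng.integers(1, 3))
            out = ops.morphological_close(m, it)
            assert np.all(out.pixels | ~m.pixels)  # output superset of input
            np.testing.assert_array_equal(out.pixels, close_naive(m.pixels, it))

    def test_empty_mask_stays_empty(self):
        out = ops.morphological_close(BinaryMask(np.zeros((6, 6), dtype=bool)))
        assert not out.pixels.any()

    def test_fill_ring_becomes_disk(self):
        ring = disk_mask(21, 21, 10, 10, 8) & ~disk_mask(21, 21, 10, 10, 7)
        out = ops.fill_holes(BinaryMask(ring))
        assert out.pixels[10, 10]
        np.testing.assert_array_equal(out.pixels, fill_holes_naive(ring))

    def test_fill_open_c_shape_unchanged(self):
        ring = disk_mask(21, 21, 10, 10, 8) & ~disk_mask(21, 21, 10, 10, 5)
        ring[9:12, 13:] = False  # open channel to the border
        out = ops.fill_holes(BinaryMask(ring))
        np.testing.assert_array_equal(out.pixels, ring)

    def test_fill_matches_flood_oracle_and_idempotent(self, rng):
        for _ in range(10):
            m = random_mask(rng, max_side=16, p=0.5)
            out = ops.fill_holes(m)
            np.testing.assert_array_equal(out.pixels, fill_holes_naive(m.pixels))
            np.testing.assert_array_equal(ops.fill_holes(out).pixels, out.pixels)

    def test_full_frame_foreground_unchanged(self):
        m = BinaryMask(np.ones((5, 7), dtype=bool))
        np.testing.assert_array_equal(ops.fill_holes(m).pixels, m.pixels)


class TestRankFilter:
    def test_maximum_grows_pixel_to_disk(self):
        m = np.zeros((11, 11), dtype=bool)
        m[5, 5] = True
        out = ops.rank_filter(BinaryMask(m), 2, "maximum")
        np.testing.assert_array_equal(out.pixels, disk_mask(11, 11, 5, 5, 2.5))

    def test_max_then_min_recovers_large_disk(self):
        m = BinaryMask(disk_mask(31, 31, 15, 15, 10))
        out = ops.rank_filter(ops.rank_filter(m, 3, "maximum"), 3, "minimum")
        np.testing.assert_array_equal(out.pixels, m.pixels)

    def test_minimum_erases_thin_object(self):
        m = np.zeros((11, 11), dtype=bool)
        m[5, 2:9] = True  # 1-px bar
        out = ops.rank_filter(BinaryMask(m), 1, "minimum")
        assert not out.pixels.any()

    def test_matches_window_oracle(self, rng):
        for _ in range(6):
            r = random_raster(rng, max_side=16)
            radius = int(rng.integers(1, 4))
            for mode in ("maximum", "minimum"):
                want = rank_filter_naive(r.pixels, radius, mode)
                np.testing.assert_allclose(
                    ops.rank_filter(r, radius, mode).pixels, want
                )

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            ops.rank_filter(Raster(np.zeros((3, 3))), 1, "median")


class TestRemoveOutliers:
    def test_isolated_speck_removed(self):
        m = np.zeros((9, 9), dtype=bool)
        m[4, 4] = True
        out = ops.remove_outliers(BinaryMask(m), 2, 50, "bright")
        assert not out.pixels.any()

    def test_solid_block_interior_preserved(self):
        m = np.zeros((15, 15), dtype=bool)
        m[3:12, 3:12] = True
        out = ops.remove_outliers(BinaryMask(m), 2, 50, "bright")
        assert out.pixels[5:10, 5:10].all()

    def test_dark_polarity_ignores_bright_specks(self):
        m = np.zeros((9, 9), dtype=bool)
        m[4, 4] = True
        out = ops.remove_outliers(BinaryMask(m), 2, 50, "dark")
        np.testing.assert_array_equal(out.pixels, m)

    def test_matches_sliding_median_oracle(self, rng):
        for _ in range(6):
            r = random_raster(rng, max_side=14)
            radius = int(rng.integers(1, 4))
            thr = float(rng.uniform(10, 90))
            pol = "bright" if rng.random() < 0.5 else "dark"
            want = remove_outliers_naive(r.pixels, radius, thr, pol)
            np.testing.assert_allclose(
                ops.remove_outliers(r, radius, thr, pol).pixels, want
            )

    def test_anti_extensive_on_binary_bright(self, rng):
        m = random_mask(rng)
        out = ops.remove_outliers(m, 2, 50, "bright")
        assert np.all(m.pixels | ~out.pixels)  # output subset of input


class TestDimensionAndCalibrationPreserved:
    @pytest.mark.parametrize(
        "op",
        [
            lambda r: ops.subtract_background(r, 3, shrink=1),
            ops.sharpen,
            lambda r: ops.enhance_contrast(r, 0.01),
            ops.sobel_edges,
            lambda r: ops.gaussian_blur(r, 1.0),
            lambda r: ops.rank_filter(r, 2, "maximum"),
            lambda r: ops.remove_outliers(r, 2, 50, "bright"),
            ops.invert,
        ],
    )
    def test_raster_ops(self, op, rng):
        r = Raster(rng.integers(0, 255, (11, 17)).astype(float), calibration=2.5)
        out = op(r)
        assert out.shape == (11, 17)
        assert out.calibration == 2.5
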