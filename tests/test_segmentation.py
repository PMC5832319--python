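import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cellquant import (
    GLOBAL_THRESHOLD,
    ParameterError,
    SegmentationParams,
    gaussian_smooth,
    make_tile_grid,
    ridler_calvard_threshold,
    segment_image,
    segment_tile,
)
from tests.oracles import iou, isodata_fixed_partitions, isodata_iterate


class TestTileGrid:
    def test_exact_division(self):
        grid = make_tile_grid(600, 600, 6, 6)
        heights = np.diff(grid.row_bounds)
        widths = np.diff(grid.col_bounds)
        assert np.all(heights == 100) and np.all(widths == 100)

    def test_remainder_spread_over_first_tiles(self):
        grid = make_tile_grid(601, 600, 6, 6)
        assert list(np.diff(grid.row_bounds)) == [101, 100, 100, 100, 100, 100]

    def test_more_tiles_than_pixels_rejected(self):
        with pytest.raises(ParameterError):
            make_tile_grid(5, 5, 6, 6)

    @given(
        h=st.integers(1, 200),
        w=st.integers(1, 200),
        r=st.integers(1, 12),
        c=st.integers(1, 12),
    )
    def test_tiles_partition_the_image_exactly(self, h, w, r, c):
        if r > h or c > w:
            with pytest.raises(ParameterError):
                make_tile_grid(h, w, r, c)
            return
        grid = make_tile_grid(h, w, r, c)
        assert grid.row_bounds[0] == 0 and grid.row_bounds[-1] == h
        assert grid.col_bounds[0] == 0 and grid.col_bounds[-1] == w
        heights = np.diff(grid.row_bounds)
        widths = np.diff(grid.col_bounds)
        assert heights.min() >= 1 and heights.max() - heights.min() <= 1
        assert widths.min() >= 1 and widths.max() - widths.min() <= 1
        covered = np.zeros((h, w), dtype=int)
        for r0, r1, c0, c1 in grid.tiles():
            covered[r0:r1, c0:c1] += 1
        assert np.all(covered == 1)


class TestRidlerCalvard:
    def test_uniform_tile_returns_its_constant(self):
        assert ridler_calvard_threshold(np.full((5, 5), 40.0)) == 40.0

    def test_bimodal_fixture_converges_to_class_midpoint(self):
        tile = np.concatenate([np.zeros(100), np.full(300, 200.0)])
        assert ridler_calvard_threshold(tile) == pytest.approx(100.0)
        assert isodata_iterate(tile) == pytest.approx(100.0)

    def test_trimodal_fixture_fixed_point(self):
        tile = np.concatenate([np.full(50, 10.0), np.full(50, 12.0), np.full(100, 240.0)])
        assert ridler_calvard_threshold(tile) == pytest.approx(125.5)
        assert isodata_iterate(tile) == pytest.approx(125.5)

    def test_empty_tile_rejected(self):
        with pytest.raises(ParameterError):
            ridler_calvard_threshold(np.array([]))

    @given(st.integers(0, 2**31 - 1))
    def test_threshold_is_an_isodata_fixed_point_of_the_data(self, seed):
        """Random bimodal uint8 tiles: the returned threshold must induce
        one of the fixed-point partitions found by exhaustive integer scan."""
        rng = np.random.default_rng(seed)
        sep = rng.uniform(10, 150)
        lo = rng.uniform(20, 100)
        tile = np.concatenate(
            [
                rng.normal(lo, rng.uniform(2, 15), 120),
                rng.normal(lo + sep, rng.uniform(2, 15), 136),
            ]
        )
        tile = np.clip(np.rint(tile), 0, 255)
        t = ridler_calvard_threshold(tile, max_iter=500, tol=1e-9)
        assert tile.min() <= t <= tile.max()
        partitions = isodata_fixed_partitions(tile)
        assert partitions, "oracle found no fixed point"
        assert any(np.array_equal(tile <= t, p) for p in partitions)

    def test_partition_agrees_with_skimage_isodata(self, rng):
        """Independent cross-check: on well-separated bimodal 8-bit data
        the induced cell/background partition matches scikit-image's
        histogram-based ISODATA threshold."""
        from skimage.filters import threshold_isodata

        for _ in range(25):
            sep = rng.uniform(40, 160)
            lo = rng.uniform(20, 80)
            tile = np.clip(
                np.rint(
                    np.concatenate(
                        [rng.normal(lo, 8, 150), rng.normal(lo + sep, 8, 150)]
                    )
                ),
                0,
                255,
            ).astype(np.uint8)
            t_sk = threshold_isodata(tile)
            t = ridler_calvard_threshold(tile.astype(float), max_iter=500, tol=1e-9)
            assert np.array_equal(tile <= t, tile <= t_sk)


class TestGaussianSmooth:
    def test_constant_tile_unchanged_for_any_sigma(self):
        tile = np.full((20, 20), 87.5)
        assert np.allclose(gaussian_smooth(tile, 6.0), tile)

    def test_sigma_zero_is_identity(self, rng):
        tile = rng.uniform(0, 255, (15, 15))
        assert np.array_equal(gaussian_smooth(tile, 0.0), tile)

    def test_impulse_response_is_normalized_and_centered(self):
        tile = np.zeros((101, 101))
        tile[50, 50] = 1.0
        out = gaussian_smooth(tile, 3.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.unravel_index(out.argmax(), out.shape) == (50, 50)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ParameterError):
            gaussian_smooth(np.zeros((3, 3)), -1.0)


def _disk_tile(size=100, radius=18, bg=200.0, fg=60.0):
    yy, xx = np.mgrid[0:size, 0:size]
    disk = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= radius**2
    tile = np.full((size, size), bg)
    tile[disk] = fg
    return tile, disk


class TestSegmentTile:
    def test_dark_disk_recovered_with_coverage_tolerance(self):
        tile, disk = _disk_tile()
        mask = segment_tile(tile, SegmentationParams())
        truth_pct = 100 * disk.mean()
        got_pct = 100 * mask.mean()
        assert got_pct == pytest.approx(truth_pct, abs=2.0)
        # the found foreground is essentially the disk, not scattered noise
        assert iou(mask, disk) > 0.85

    def test_uniform_tile_yields_no_cells(self):
        mask = segment_tile(np.full((50, 50), 120.0), SegmentationParams())
        assert not mask.any()

    def test_polarity_symmetry_on_inverted_fixture(self):
        tile, disk = _disk_tile()
        inverted = 255.0 - tile
        mask_dark = segment_tile(tile, SegmentationParams())
        mask_bright = segment_tile(inverted, SegmentationParams(polarity="bright_cells"))
        assert np.array_equal(mask_dark, mask_bright)

    def test_low_contrast_noise_tile_yields_no_cells(self, rng):
        # blank background with pixel noise and a mild internal ramp: the
        # class-separation guard must refuse to call half of it "cells"
        tile = 180.0 + np.linspace(0, 10, 100)[None, :] + rng.normal(0, 3, (100, 100))
        assert not segment_tile(tile, SegmentationParams()).any()


class TestSegmentImage:
    def _gradient_scene(self, rng, n_cells=40):
        h = w = 300
        img = np.linspace(120, 230, w)[None, :] * np.ones((h, 1))
        truth = np.zeros((h, w), dtype=bool)
        for _ in range(n_cells):
            cy, cx = rng.integers(15, h - 15), rng.integers(15, w - 15)
            yy, xx = np.mgrid[0:h, 0:w]
            truth |= (yy - cy) ** 2 + (xx - cx) ** 2 <= 14**2
        img = np.where(truth, img - 50, img) + rng.normal(0, 2, (h, w))
        return np.clip(img, 0, 255), truth

    def test_tiling_beats_global_threshold_under_gradient(self, rng):
        img, truth = self._gradient_scene(rng)
        tiled = segment_image(img, SegmentationParams())
        global_ = segment_image(img, GLOBAL_THRESHOLD)
        assert iou(tiled, truth) >= 0.7
        assert iou(tiled, truth) > iou(global_, truth)

    def test_blank_gradient_image_measures_below_one_percent(self, rng):
        img = np.linspace(150, 210, 300)[None, :] * np.ones((300, 1))
        img = img + rng.normal(0, 3, (300, 300))
        mask = segment_image(np.clip(img, 0, 255), SegmentationParams())
        assert 100 * mask.mean() < 1.0

    def test_deterministic_for_fixed_input(self, rng):
        img, _ = self._gradient_scene(rng)
        params = SegmentationParams()
        assert np.array_equal(segment_image(img, params), segment_image(img, params))

    def test_output_shape_matches_input(self, rng):
        img = rng.uniform(0, 255, (121, 97))
        assert segment_image(img, SegmentationParams(grid_rows=4, grid_cols=3)).shape == (121, 97)

    def test_darkening_foreground_pixels_keeps_them_foreground(self):
        # monotonicity at sigma 0: pixels already far below the threshold
        # stay foreground when pushed further down
        tile, disk = _disk_tile()
        params = SegmentationParams(sigma_px=0.0)
        before = segment_tile(tile, params)
        darker = tile.copy()
        darker[disk] -= 40.0
        after = segment_tile(np.clip(darker, 0, 255), params)
        assert np.all(after[before & disk])
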