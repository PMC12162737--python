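"""Tile grids, parametric maps, and ROI readout."""

from __future__ import annotations

import numpy as np
import pytest

import radiomaps as rm
from radiomaps.features import ALL_FEATURES, ExtractionSettings, extract_all
from radiomaps.maps import (
    build_tile_grid,
    compute_all_maps,
    compute_feature_map,
    map_roi_mean,
)


def _image(pixels, spacing=(1.5, 1.5)):
    return rm.ImageSlice(np.asarray(pixels, dtype=float), spacing)


class TestTileGrid:
    @pytest.mark.parametrize(
        "spacing,tile_mm,expected_px",
        [
            ((1.5, 1.5), 3.0, 2),  # round(2.0)
            ((329 / 224, 329 / 224), 3.0, 2),  # round(2.042)
            ((2.5, 2.5), 3.0, 1),  # round(1.2)
            ((8.0, 8.0), 3.0, 1),  # clamped to >= 1
        ],
    )
    def test_mm_to_pixel_rounding(self, spacing, tile_mm, expected_px):
        img = _image(np.zeros((16, 16)), spacing)
        grid = build_tile_grid(img, (tile_mm, tile_mm, 8.0))
        assert grid.tile_size_px == (expected_px, expected_px)

    def test_tile_larger_than_image_gives_single_tile(self):
        img = _image(np.zeros((8, 6)), (1.0, 1.0))
        grid = build_tile_grid(img, (100.0, 100.0, 8.0))
        assert grid.n_tiles == (1, 1)
        assert list(grid.tile_slices()) == [(slice(0, 8), slice(0, 6))]

    def test_tiles_partition_the_pixel_grid(self):
        img = _image(np.zeros((11, 7)), (1.0, 1.0))
        grid = build_tile_grid(img, (3.0, 3.0, 8.0))
        covered = np.zeros((11, 7), dtype=int)
        for rs, cs in grid.tile_slices():
            covered[rs, cs] += 1
        assert (covered == 1).all()


class TestMapComputation:
    def test_single_tile_identity_with_conventional(self):
        rng = np.random.default_rng(21)
        img = _image(rng.uniform(0, 160, size=(10, 12)))
        mask = rm.SegmentationMask.like(img, np.ones((10, 12), bool))
        grid = build_tile_grid(img, (1000.0, 1000.0, 8.0))
        fv = extract_all(img, mask)
        maps = compute_all_maps(img, grid)
        for name in ALL_FEATURES:
            pm = maps[name]
            if fv.valid[name]:
                assert pm.valid.all()
                # exact identity, tolerance zero: shared code path
                assert (pm.values == fv[name]).all(), name
            else:
                assert not pm.valid.any(), name

    def test_constant_image_variance_map_is_zero(self):
        img = _image(np.full((8, 8), 50.0), (1.5, 1.5))
        grid = build_tile_grid(img)
        pm = compute_feature_map(img, grid, "firstorder_Variance")
        assert (pm.values == 0.0).all()
        assert pm.valid.all()

    def test_two_tile_mean_map(self):
        # tiles of 2x2 at 1.5mm: left tile constant 10, right tile constant 20
        px = np.array([[10.0, 10, 20, 20], [10, 10, 20, 20]])
        img = _image(px, (1.5, 1.5))
        grid = build_tile_grid(img)
        assert grid.n_tiles == (1, 2)
        pm = compute_feature_map(img, grid, "firstorder_Mean")
        np.testing.assert_array_equal(pm.values, px)

    def test_locality_of_tile_edits(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 100, size=(6, 6))
        img_a = _image(base, (1.5, 1.5))
        changed = base.copy()
        changed[0:2, 0:2] += 37.0  # exactly the first 2x2 tile
        img_b = _image(changed, (1.5, 1.5))
        grid = build_tile_grid(img_a)
        pa = compute_feature_map(img_a, grid, "firstorder_Mean").values
        pb = compute_feature_map(img_b, grid, "firstorder_Mean").values
        diff = pa != pb
        assert diff[0:2, 0:2].all()
        assert not diff[2:, :].any() and not diff[:2, 2:].any()

    def test_all_maps_count_and_determinism(self):
        rng = np.random.default_rng(5)
        img = _image(rng.uniform(0, 160, size=(12, 10)))
        grid = build_tile_grid(img)
        maps_a = compute_all_maps(img, grid)
        maps_b = compute_all_maps(img, grid)
        assert len(maps_a) == 93
        for name in maps_a:
            np.testing.assert_array_equal(
                maps_a[name].values[maps_a[name].valid],
                maps_b[name].values[maps_b[name].valid],
            )

    def test_unknown_feature_name_errors(self):
        img = _image(np.zeros((4, 4)))
        grid = build_tile_grid(img)
        with pytest.raises(KeyError, match="firstorder_Mean"):
            compute_feature_map(img, grid, "nonsense_Feature")

    def test_geometry_is_preserved(self):
        img = _image(np.zeros((6, 8)), (1.25, 2.0))
        grid = build_tile_grid(img)
        pm = compute_feature_map(img, grid, "firstorder_Mean")
        assert pm.spacing_mm == img.spacing_mm
        assert pm.origin_mm == img.origin_mm
        assert pm.to_image().spacing_mm == img.spacing_mm


class TestMapReadout:
    def test_uniform_map(self):
        img = _image(np.full((4, 4), 7.0))
        grid = build_tile_grid(img, (1.5, 1.5, 8.0))
        pm = compute_feature_map(img, grid, "firstorder_Mean")
        mask = rm.SegmentationMask.like(img, np.ones((4, 4), bool))
        ro = map_roi_mean(pm, mask)
        assert ro.value == 7.0
        assert ro.invalid_fraction == 0.0

    def test_half_and_half_average(self):
        pm = compute_feature_map(
            _image(np.array([[10.0, 10, 20, 20], [10, 10, 20, 20]]), (1.5, 1.5)),
            build_tile_grid(_image(np.zeros((2, 4)), (1.5, 1.5))),
            "firstorder_Mean",
        )
        mask = rm.SegmentationMask(np.ones((2, 4), bool), (1.5, 1.5))
        assert map_roi_mean(pm, mask).value == pytest.approx(15.0)

    def test_mask_straddling_invalid_tiles(self):
        # left tile constant (correlation undefined), right tile textured
        px = np.array([[5.0, 5, 0, 25], [5, 5, 50, 75]])
        img = _image(px, (1.5, 1.5))
        grid = build_tile_grid(img)
        pm = compute_feature_map(img, grid, "glcm_Correlation")
        mask = rm.SegmentationMask.like(img, np.ones((2, 4), bool))
        ro = map_roi_mean(pm, mask)
        assert ro.valid
        assert ro.invalid_fraction == pytest.approx(0.5)
        np.testing.assert_allclose(ro.value, pm.values[0, 2])

    def test_fully_invalid_readout_is_flagged(self):
        img = _image(np.full((2, 2), 5.0), (1.5, 1.5))
        pm = compute_feature_map(img, build_tile_grid(img), "glcm_Correlation")
        mask = rm.SegmentationMask.like(img, np.ones((2, 2), bool))
        ro = map_roi_mean(pm, mask)
        assert not ro.valid
        assert ro.invalid_fraction == 1.0

    def test_empty_mask_errors(self):
        img = _image(np.zeros((2, 2)))
        pm = compute_feature_map(img, build_tile_grid(img), "firstorder_Mean")
        mask = rm.SegmentationMask.like(img, np.zeros((2, 2), bool))
        with pytest.raises(ValueError, match="empty"):
            map_roi_mean(pm, mask)
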