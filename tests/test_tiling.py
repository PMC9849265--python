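"""Tile geometry: coverage, core partition, ownership, merge, and splits."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mosaicount as mc
from mosaicount.errors import BoundsError, ConfigurationError

from conftest import make_set


class TestPlanGrid:
    def test_single_tile_exact_fit(self):
        g = mc.plan_grid(mc.MosaicMeta("m", 1000, 1000))
        assert (g.nx, g.ny) == (1, 1)
        t = g.tile(0, 0)
        assert t.extent == mc.BoundingBox(0, 0, 1000, 1000)
        assert t.core == t.extent

    def test_wide_mosaic_three_tiles(self):
        g = mc.plan_grid(mc.MosaicMeta("m", 2800, 1000))
        assert (g.nx, g.ny) == (3, 1)
        assert [t.extent.x0 for t in g.tiles()] == [0, 900, 1800]
        assert g.tile(2, 0).extent == mc.BoundingBox(1800, 0, 2800, 1000)

    def test_small_mosaic_clipped(self):
        g = mc.plan_grid(mc.MosaicMeta("m", 950, 950))
        assert g.n_tiles == 1
        assert g.tile(0, 0).extent == mc.BoundingBox(0, 0, 950, 950)

    def test_overlap_must_be_less_than_tile(self):
        with pytest.raises(ConfigurationError):
            mc.TileGrid("m", 1000, 1000, tile_size=1000, overlap=1000)

    @given(st.integers(50, 5000), st.integers(50, 5000))
    def test_coverage_and_core_partition(self, width, height):
        """Extents cover every pixel; cores tile the mosaic disjointly."""
        g = mc.TileGrid("m", width, height, tile_size=300, overlap=40)
        x_ext = np.zeros(width, int)
        x_core = np.zeros(width, int)
        for i in range(g.nx):
            t = g.tile(i, 0)
            x_ext[t.extent.x0:t.extent.x1] += 1
            x_core[t.core.x0:t.core.x1] += 1
        y_core = np.zeros(height, int)
        for j in range(g.ny):
            t = g.tile(0, j)
            y_core[t.core.y0:t.core.y1] += 1
        assert (x_ext >= 1).all()
        assert (x_core == 1).all() and (y_core == 1).all()

    @given(st.integers(301, 4000), st.integers(1, 500))
    def test_tile_count_monotone_in_width(self, width, extra):
        kw = dict(tile_size=300, overlap=40)
        assert (mc.TileGrid("m", width + extra, 300, **kw).nx
                >= mc.TileGrid("m", width, 300, **kw).nx)


class TestOwnership:
    def test_interior_box_stays_in_first_tile(self, grid_2800):
        owned = mc.assign_to_tiles(grid_2800, make_set([(50, 50, 120, 120)]))
        assert list(owned) == [(0, 0)]
        assert owned[(0, 0)][0].bbox == mc.BoundingBox(50, 50, 120, 120)

    def test_box_in_overlap_band_owned_by_next_tile(self, grid_2800):
        owned = mc.assign_to_tiles(grid_2800, make_set([(950, 10, 1030, 60)]))
        assert list(owned) == [(1, 0)]
        tile = grid_2800.tile(1, 0)
        local = owned[(1, 0)][0].bbox
        assert local == mc.BoundingBox(50, 10, 130, 60)
        assert mc.tile_to_mosaic(tile, local) == mc.BoundingBox(950, 10, 1030, 60)

    def test_box_crossing_core_boundary_kept_by_left_owner(self, grid_2800):
        owned = mc.assign_to_tiles(grid_2800, make_set([(890, 10, 960, 60)]))
        assert list(owned) == [(0, 0)]
        local = owned[(0, 0)][0].bbox
        assert local.x1 <= grid_2800.tile(0, 0).extent.width

    def test_out_of_bounds_annotation_rejected(self, grid_2800):
        with pytest.raises(BoundsError):
            mc.assign_to_tiles(grid_2800, make_set([(2700, 900, 2900, 1100)]))


class TestFrameTransforms:
    def test_translation_example(self, grid_2800):
        tile = grid_2800.tile(1, 0)
        local = mc.BoundingBox(50, 10, 130, 60)
        assert mc.tile_to_mosaic(tile, local) == mc.BoundingBox(950, 10, 1030, 60)

    def test_origin_tile_is_identity(self, grid_2800):
        tile = grid_2800.tile(0, 0)
        b = mc.BoundingBox(3, 4, 20, 30)
        assert mc.tile_to_mosaic(tile, b) == b

    @given(st.integers(0, 2), st.integers(0, 800), st.integers(0, 800),
           st.integers(1, 99), st.integers(1, 99))
    def test_round_trip_inverse(self, i, x, y, w, h):
        grid = mc.TileGrid("m1", 2800, 1000)
        tile = grid.tile(i, 0)
        local = mc.BoundingBox(x, y, x + w, y + h)
        assert mc.mosaic_to_tile(tile, mc.tile_to_mosaic(tile, local)) == local


class TestMerge:
    def test_duplicate_in_overlap_band_kept_once(self, grid_2800):
        # tiles (0,0) and (1,0) both report the animal at mosaic [950,10,1020,60)
        per_tile = {
            (0, 0): make_set([(950, 10, 1020, 60)]),
            (1, 0): make_set([(50, 10, 120, 60)]),
        }
        merged = mc.merge_tile_detections(grid_2800, per_tile)
        assert len(merged) == 1
        assert merged[0].bbox == mc.BoundingBox(950, 10, 1020, 60)

    def test_core_detections_all_retained(self, grid_2800):
        per_tile = {
            (0, 0): make_set([(10, 10, 60, 60), (500, 500, 560, 560)]),
            (2, 0): make_set([(300, 300, 360, 360)]),
        }
        merged = mc.merge_tile_detections(grid_2800, per_tile)
        assert len(merged) == 3

    def test_nms_keeps_highest_confidence(self, grid_2800):
        per_tile = {(0, 0): make_set(
            [(100, 100, 200, 200), (105, 100, 205, 200)],
            ["adult", "adult"], confs=[0.8, 0.6])}
        merged = mc.merge_tile_detections(grid_2800, per_tile, nms_iou=0.5)
        assert len(merged) == 1
        assert merged[0].confidence == 0.8

    def test_nms_spares_different_labels(self, grid_2800):
        per_tile = {(0, 0): make_set(
            [(100, 100, 200, 200), (105, 100, 205, 200)],
            ["adult", "ghost"], confs=[0.8, 0.6])}
        assert len(mc.merge_tile_detections(grid_2800, per_tile, nms_iou=0.5)) == 2

    @given(st.lists(
        st.tuples(st.integers(0, 2699), st.integers(0, 899),
                  st.integers(1, 100), st.integers(1, 100),
                  st.sampled_from(["adult", "calf", "ghost"])),
        max_size=25))
    def test_assign_then_merge_is_identity(self, rows):
        """Ownership round trip conserves every box with sides <= overlap."""
        grid = mc.TileGrid("m1", 2800, 1000)
        rows = [(x, y, w, h, l) for x, y, w, h, l in rows
                if x + w <= 2800 and y + h <= 1000]
        aset = make_set([(x, y, x + w, y + h) for x, y, w, h, _ in rows],
                        [l for *_, l in rows])
        merged = mc.merge_tile_detections(grid, mc.assign_to_tiles(grid, aset))
        assert sorted((a.bbox, a.label) for a in merged) == \
            sorted((a.bbox, a.label) for a in aset)


class TestSplit:
    def test_75_25_split(self):
        grid = mc.TileGrid("m", 4600, 9100, tile_size=1000, overlap=100)
        assert grid.n_tiles == 50
        train, test = mc.split_tiles(grid, 0.75, seed=0)
        assert (len(train), len(test)) == (38, 12)  # 37.5 rounds up
        assert set(train).isdisjoint(test)
        assert len(set(train) | set(test)) == 50

    def test_determinism(self):
        grid = mc.TileGrid("m", 5000, 5000)
        a = mc.split_tiles(grid, 0.75, seed=7)
        b = mc.split_tiles(grid, 0.75, seed=7)
        assert a == b
        c = mc.split_tiles(grid, 0.75, seed=8)
        assert a != c

    def test_stratified_proportions_per_mosaic(self):
        # four mosaics of 10 tiles each; 0.75 of 10 rounds to 8 (ties up)
        grids = [mc.TileGrid(f"m{k}", 4600, 1900, 1000, 100) for k in range(4)]
        assert all(g.n_tiles == 10 for g in grids)
        train, _ = mc.split_tiles(grids, 0.75, seed=1)
        for g in grids:
            n = sum(1 for m, _ in train if m == g.mosaic_id)
            assert n == 8

    def test_bad_fraction(self):
        with pytest.raises(ConfigurationError):
            mc.split_tiles(mc.TileGrid("m", 2000, 2000), 1.5, seed=0)
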