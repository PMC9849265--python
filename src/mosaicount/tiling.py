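"""Overlap-aware tiling of large orthomosaics.

Detectors cannot ingest a 50k x 50k pixel mosaic, so the mosaic is cut into
fixed-size tiles (default 1000 x 1000 px) that overlap their right and lower
neighbours by a fixed band (default 100 px).  The overlap guarantees that an
animal cut by a tile boundary appears whole in at least one tile — provided
its box is no larger than the overlap — so it can be counted exactly once.

Unique counting is enforced by the *core* partition: each tile owns the
disjoint ``stride x stride`` region at its top-left (``stride = tile_size -
overlap``); the last tile along each axis owns the remainder up to the mosaic
edge.  An annotation belongs to the tile whose core contains its top-left
corner.  Merging per-tile detections back to mosaic coordinates keeps a
detection only if the emitting tile owns it, which makes the
assign -> report -> merge round trip count-conserving.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .annotations import Annotation, AnnotationSet, BoundingBox, MosaicMeta, box_iou
from .errors import BoundsError, ConfigurationError

__all__ = [
    "Tile",
    "TileGrid",
    "plan_grid",
    "assign_to_tiles",
    "tile_to_mosaic",
    "mosaic_to_tile",
    "merge_tile_detections",
    "split_tiles",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Tile:
    """One tile: full extent (what a detector sees) and disjoint core (what it owns)."""

    index: tuple[int, int]
    extent: BoundingBox
    core: BoundingBox

    @property
    def origin(self) -> tuple[int, int]:
        return (self.extent.x0, self.extent.y0)


def _axis_tile_count(dim: int, tile_size: int, overlap: int) -> int:
    stride = tile_size - overlap
    return max(1, math.ceil((dim - overlap) / stride))


@dataclass(frozen=True)
class TileGrid:
    """Deterministic tiling geometry for one mosaic."""

    mosaic_id: str
    width: int
    height: int
    tile_size: int = 1000
    overlap: int = 100

    def __post_init__(self):
        if not (0 < self.overlap < self.tile_size):
            raise ConfigurationError(
                f"require 0 < overlap < tile_size, got overlap={self.overlap}, "
                f"tile_size={self.tile_size}"
            )
        if self.width <= 0 or self.height <= 0:
            raise ConfigurationError("mosaic dimensions must be positive")

    @property
    def stride(self) -> int:
        return self.tile_size - self.overlap

    @property
    def nx(self) -> int:
        return _axis_tile_count(self.width, self.tile_size, self.overlap)

    @property
    def ny(self) -> int:
        return _axis_tile_count(self.height, self.tile_size, self.overlap)

    @property
    def n_tiles(self) -> int:
        return self.nx * self.ny

    def tile(self, i: int, j: int) -> Tile:
        if not (0 <= i < self.nx and 0 <= j < self.ny):
            raise IndexError(f"tile index ({i},{j}) outside grid {self.nx}x{self.ny}")
        s = self.stride
        ex0, ey0 = i * s, j * s
        ex1 = min(ex0 + self.tile_size, self.width)
        ey1 = min(ey0 + self.tile_size, self.height)
        # last tile's core runs to the mosaic edge so cores partition the mosaic
        cx1 = self.width if i == self.nx - 1 else (i + 1) * s
        cy1 = self.height if j == self.ny - 1 else (j + 1) * s
        return Tile((i, j), BoundingBox(ex0, ey0, ex1, ey1), BoundingBox(ex0, ey0, cx1, cy1))

    def tiles(self) -> list[Tile]:
        """All tiles in row-major order (j outer, i inner)."""
        return [self.tile(i, j) for j in range(self.ny) for i in range(self.nx)]

    def owner_index(self, x0: int, y0: int) -> tuple[int, int]:
        """Index of the tile whose core contains the point (x0, y0)."""
        if not (0 <= x0 < self.width and 0 <= y0 < self.height):
            raise BoundsError(f"point ({x0},{y0}) outside mosaic "
                              f"{self.width}x{self.height}")
        return (min(x0 // self.stride, self.nx - 1),
                min(y0 // self.stride, self.ny - 1))


def plan_grid(meta: MosaicMeta, tile_size: int = 1000, overlap: int = 100) -> TileGrid:
    """Plan the tile grid for a mosaic.

    Tiles start at multiples of ``stride = tile_size - overlap``; the count
    per axis is the smallest whose union covers the axis,
    ``max(1, ceil((dim - overlap) / stride))``, and the final row/column is
    clipped to the mosaic boundary rather than padded.
    """
    return TileGrid(meta.mosaic_id, meta.width, meta.height, tile_size, overlap)


def assign_to_tiles(grid: TileGrid, aset: AnnotationSet
                    ) -> dict[tuple[int, int], AnnotationSet]:
    """Assign each annotation to its unique owner tile, in tile-local coordinates.

    The owner is the tile whose core contains the box's top-left corner.  A box
    whose sides are <= the overlap is guaranteed to lie fully inside its
    owner's extent; larger boxes are kept (and a warning logged) even where
    they overhang the extent.
    """
    out: dict[tuple[int, int], AnnotationSet] = {}
    for ann in aset:
        ann.bbox.check_within(grid.width, grid.height)
        idx = grid.owner_index(ann.bbox.x0, ann.bbox.y0)
        tile = grid.tile(*idx)
        local = ann.bbox.translate(-tile.extent.x0, -tile.extent.y0)
        if (local.x1 > tile.extent.width or local.y1 > tile.extent.height):
            logger.warning(
                "annotation %s (sides %dx%d) overhangs owner tile %s extent; "
                "kept unclipped", ann.bbox, ann.bbox.width, ann.bbox.height, idx,
            )
        if idx not in out:
            out[idx] = AnnotationSet(aset.mosaic_id, aset.source_id, [])
        out[idx].annotations.append(Annotation(local, ann.label, ann.confidence))
    return out


def tile_to_mosaic(tile: Tile, local: BoundingBox) -> BoundingBox:
    """Translate a tile-local box to mosaic coordinates."""
    return local.translate(tile.extent.x0, tile.extent.y0)


def mosaic_to_tile(tile: Tile, mosaic_box: BoundingBox) -> BoundingBox:
    """Translate a mosaic-frame box into the tile's local frame."""
    if (mosaic_box.x0 < tile.extent.x0 or mosaic_box.y0 < tile.extent.y0):
        raise BoundsError(f"box {mosaic_box} starts before tile origin {tile.origin}")
    return mosaic_box.translate(-tile.extent.x0, -tile.extent.y0)


def merge_tile_detections(grid: TileGrid,
                          per_tile: Mapping[tuple[int, int], AnnotationSet],
                          nms_iou: Optional[float] = None) -> AnnotationSet:
    """Merge per-tile detections into one mosaic-frame set without double counting.

    A detection is retained only if the tile that emitted it is its owner
    under the top-left-corner rule; detections of the same animal reported by
    a neighbouring tile's overlap band are dropped.  If *nms_iou* is given,
    same-label survivors with pairwise IoU >= nms_iou are additionally
    suppressed, keeping the highest-confidence one.
    """
    mosaic_id = ""
    source_id = "merged"
    survivors: list[Annotation] = []
    for idx in sorted(per_tile):
        tile_set = per_tile[idx]
        if tile_set.mosaic_id:
            mosaic_id = tile_set.mosaic_id
            source_id = tile_set.source_id
        tile = grid.tile(*idx)
        for ann in tile_set:
            mos_box = tile_to_mosaic(tile, ann.bbox)
            if mos_box.x1 > grid.width or mos_box.y1 > grid.height:
                # spurious detection hanging off the mosaic edge
                continue
            if grid.owner_index(mos_box.x0, mos_box.y0) == idx:
                survivors.append(Annotation(mos_box, ann.label, ann.confidence))
    if nms_iou is not None:
        survivors = _nms(survivors, nms_iou)
    return AnnotationSet(mosaic_id or grid.mosaic_id, source_id, survivors)


def _nms(annotations: Sequence[Annotation], nms_iou: float) -> list[Annotation]:
    """Greedy per-label non-maximum suppression, highest confidence first."""
    kept: list[Annotation] = []
    order = sorted(
        range(len(annotations)),
        key=lambda k: -(annotations[k].confidence
                        if annotations[k].confidence is not None else 1.0),
    )
    for k in order:
        cand = annotations[k]
        if any(kept_ann.label == cand.label
               and box_iou(kept_ann.bbox, cand.bbox) >= nms_iou
               for kept_ann in kept):
            continue
        kept.append(cand)
    # restore input order among the kept boxes
    kept_ids = {id(a) for a in kept}
    return [a for a in annotations if id(a) in kept_ids]


def split_tiles(grids: Union[TileGrid, Sequence[TileGrid]],
                fraction: float,
                seed: int,
                stratify_by_mosaic: bool = True
                ) -> tuple[list[tuple[str, tuple[int, int]]],
                           list[tuple[str, tuple[int, int]]]]:
    """Random train/test split of tiles, as ``(mosaic_id, (i, j))`` pairs.

    Deterministic given *seed*.  When stratified (default), each mosaic
    contributes ``round(fraction * n_tiles)`` training tiles (ties round up),
    so per-mosaic proportions stay within one tile of *fraction*.  Tiles with
    no annotations are ordinary members of the pool: empty tiles serve as
    negative examples on either side.
    """
    if not (0.0 < fraction < 1.0):
        raise ConfigurationError(f"fraction must be in (0,1), got {fraction}")
    if isinstance(grids, TileGrid):
        grids = [grids]
    rng = np.random.default_rng(seed)
    train: list[tuple[str, tuple[int, int]]] = []
    test: list[tuple[str, tuple[int, int]]] = []

    def _split_pool(pool: list[tuple[str, tuple[int, int]]]):
        n_train = int(math.floor(fraction * len(pool) + 0.5))
        perm = rng.permutation(len(pool))
        train.extend(pool[k] for k in perm[:n_train])
        test.extend(pool[k] for k in perm[n_train:])

    if stratify_by_mosaic:
        for grid in grids:
            _split_pool([(grid.mosaic_id, t.index) for t in grid.tiles()])
    else:
        _split_pool([(g.mosaic_id, t.index) for g in grids for t in g.tiles()])
    return train, test
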