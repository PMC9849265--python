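"""A deliberately simple, non-learned blob detector for synthetic scenes.

This is *not* a stand-in claim about CNN performance: it exists so the whole
tile -> detect -> merge -> evaluate pipeline can run end-to-end on synthetic
mosaics with no trained weights.  It estimates the local background with a
rank median filter, thresholds the positive residual (animals render brighter
than the tundra background), and classifies connected components by
GSD-scaled metric area (calf vs adult) and mean contrast (ghost if faint).

Any callable ``(tile_raster) -> AnnotationSet`` can replace it in
:func:`detect_mosaic`, which is the intended adapter seam for a real CNN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import rank

from .annotations import Annotation, AnnotationSet, BoundingBox, Label
from .errors import ConfigurationError, FrameError, InputError
from .tiling import TileGrid, merge_tile_detections

__all__ = ["DetectorConfig", "detect_tile", "detect_mosaic"]


@dataclass(frozen=True)
class DetectorConfig:
    """Tunables for the baseline detector.

    Areas are metric (m^2) and converted to pixels through the GSD, so one
    config works at both flight altitudes.  ``ghost_contrast_cut`` is mean
    foreground contrast as a fraction of full scale (255); components fainter
    than it are labeled ghost.
    """

    bg_window_px: int = 75
    z_threshold: float = 3.5
    min_area_m2: float = 0.10
    max_area_m2: float = 5.0
    calf_area_cut_m2: float = 0.55
    ghost_contrast_cut: float = 0.22
    nms_iou: float = 0.4

    def __post_init__(self):
        if not (self.min_area_m2 < self.calf_area_cut_m2 < self.max_area_m2):
            raise ConfigurationError(
                "require min_area < calf/adult area cut < max_area, got "
                f"{self.min_area_m2} / {self.calf_area_cut_m2} / {self.max_area_m2}"
            )
        if self.bg_window_px < 3:
            raise ConfigurationError("bg_window_px must be >= 3")


def detect_tile(tile_raster: np.ndarray, config: DetectorConfig,
                gsd_cm: float) -> AnnotationSet:
    """Detect bright blobs in one tile; returns tile-local annotations with confidences.

    Background is the local rank median over ``bg_window_px``; foreground is
    the residual above ``z_threshold`` robust (MAD) standard deviations.
    Components are filtered by metric area, labeled calf below the area cut
    and adult above it, then relabeled ghost if their mean contrast falls
    below ``ghost_contrast_cut``.  Confidence is normalized contrast.
    """
    img = np.asarray(tile_raster)
    if img.ndim == 3:  # RGB(A) -> luminance
        img = img[..., :3].mean(axis=2)
    if img.ndim != 2 or img.size == 0:
        raise InputError("tile raster must be a non-empty 2-D (or RGB) array")
    if gsd_cm <= 0:
        raise InputError("gsd_cm must be positive")

    img_u8 = np.clip(img, 0, 255).astype(np.uint8)
    footprint = morphology.footprint_rectangle(
        (config.bg_window_px, config.bg_window_px))
    background = rank.median(img_u8, footprint).astype(float)
    fg = img.astype(float) - background

    med = np.median(fg)
    sigma = max(1.4826 * np.median(np.abs(fg - med)), 1.0)
    mask = fg > (med + config.z_threshold * sigma)
    disk = morphology.disk(2)
    mask = ndimage.binary_opening(mask, disk)
    mask = ndimage.binary_closing(mask, disk)

    px_area_m2 = (gsd_cm / 100.0) ** 2
    min_px = config.min_area_m2 / px_area_m2
    max_px = config.max_area_m2 / px_area_m2
    cut_px = config.calf_area_cut_m2 / px_area_m2

    annotations: list[Annotation] = []
    labels = measure.label(mask)
    for region in measure.regionprops(labels, intensity_image=fg):
        if not (min_px <= region.area <= max_px):
            continue
        contrast = float(region.intensity_mean) / 255.0
        if contrast < config.ghost_contrast_cut:
            label = Label.GHOST
        elif region.area < cut_px:
            label = Label.CALF
        else:
            label = Label.ADULT
        y0, x0, y1, x1 = region.bbox  # skimage bbox is already half-open
        conf = float(np.clip(contrast * 2.5, 0.01, 1.0))
        annotations.append(Annotation(BoundingBox(x0, y0, x1, y1), label, conf))
    return AnnotationSet("", "detector", annotations)


def detect_mosaic(mosaic_raster: np.ndarray, grid: TileGrid,
                  config: DetectorConfig = DetectorConfig(),
                  gsd_cm: float = 2.4,
                  detect_fn=None) -> AnnotationSet:
    """Run the detector tile-by-tile and merge to mosaic coordinates.

    ``detect_fn`` may supply any adapter ``(tile_raster) -> AnnotationSet``
    (e.g. a trained CNN wrapper) in place of :func:`detect_tile`.  Merging
    applies the owner-tile rule and NMS at ``config.nms_iou``, so an animal
    straddling a core boundary is counted exactly once.  Deterministic.
    """
    img = np.asarray(mosaic_raster)
    if img.shape[:2] != (grid.height, grid.width):
        raise FrameError(
            f"raster shape {img.shape[:2]} does not match grid "
            f"{grid.height}x{grid.width}"
        )
    per_tile = {}
    for tile in grid.tiles():
        e = tile.extent
        crop = img[e.y0:e.y1, e.x0:e.x1]
        dets = (detect_fn(crop) if detect_fn is not None
                else detect_tile(crop, config, gsd_cm))
        dets.mosaic_id = grid.mosaic_id
        # An animal cut by this tile's leading (left/top) edge is a fragment of
        # one fully visible in the previous tile; count it there, not here.
        # Margin 3 px: binary opening erodes clipped fragments off the edge.
        i, j = tile.index
        dets.annotations = [
            a for a in dets.annotations
            if not ((i > 0 and a.bbox.x0 <= 3) or (j > 0 and a.bbox.y0 <= 3))
        ]
        per_tile[tile.index] = dets
    return merge_tile_detections(grid, per_tile, nms_iou=config.nms_iou)
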