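"""Synthetic mosaics, ground truth, and error-prone simulated annotators.

The survey imagery this pipeline was designed for is not public, so every
stage is exercised against procedurally generated scenes that reproduce the
*statistical* structure the analysis relies on, not the photographic content:

* a textured background (meadow tones, darker shrub/water patches, fine grain);
* adults and calves as high-contrast elongated blobs whose pixel size follows
  from a metric body length and the ground sampling distance, calves a
  configurable fraction of adult size;
* ghosts — the blurred, semi-transparent imprints of animals that moved
  between overlapping photos during mosaicking — as the same sprites
  composited at reduced opacity after a Gaussian blur, giving detectors and
  simulated observers a measurably harder class;
* rock / bird / trunk distractors, rendered into the raster but kept in a
  separate set: they are never reference animals, only potential spurious
  detections.

Simulated observers make the same kinds of mistakes the evaluation tallies:
they miss an animal with a per-class probability, swap its class according to
a confusion row, jitter box edges, and (for detector-like annotators) mark
distractor objects as animals.  All randomness is seeded; a scene and its
observers draw from separate streams so observers can be re-simulated without
re-rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Optional

import imageio.v3 as iio
import numpy as np
import yaml
from scipy import ndimage

from .annotations import (
    Annotation,
    AnnotationSet,
    BoundingBox,
    Label,
    LABELS,
    MosaicMeta,
    write_annotations,
)
from .errors import CapacityError, ObserverModelError

__all__ = [
    "SceneSpec",
    "ObserverModel",
    "Scene",
    "Distractor",
    "DistractorSet",
    "generate_scene",
    "simulate_observer",
    "build_fixture_suite",
]

DISTRACTOR_KINDS = ("rock", "bird", "trunk")


@dataclass(frozen=True)
class SceneSpec:
    """Generative parameters for one synthetic mosaic.

    Metric sizes are converted to pixels through ``gsd_cm`` (cm per pixel;
    2.4 corresponds to 75 m above ground with the reference survey camera,
    3.7 to 120 m).  Defaults give a mid-density herd scene.
    """

    mosaic_id: str = "scene"
    width: int = 2400
    height: int = 1800
    gsd_cm: float = 2.4
    n_adult: int = 60
    n_calf: int = 25
    n_ghost: int = 15
    n_rock: int = 12
    n_bird: int = 6
    n_trunk: int = 6
    adult_length_m: tuple[float, float] = (1.3, 2.1)
    calf_scale: tuple[float, float] = (0.5, 0.7)
    ghost_alpha: tuple[float, float] = (0.25, 0.6)
    ghost_blur_sigma_px: tuple[float, float] = (1.0, 3.0)
    min_separation_px: int = 50
    seed: int = 0

    def __post_init__(self):
        for name in ("adult_length_m", "calf_scale", "ghost_alpha",
                     "ghost_blur_sigma_px"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range must be positive and ordered")
        if self.gsd_cm <= 0:
            raise ValueError("gsd_cm must be positive")

    @property
    def px_per_m(self) -> float:
        return 100.0 / self.gsd_cm

    @property
    def altitude_agl(self) -> float:
        # nominal flight altitude implied by the GSD presets
        return 75.0 if self.gsd_cm <= 3.0 else 120.0

    def meta(self) -> MosaicMeta:
        return MosaicMeta(self.mosaic_id, self.width, self.height,
                          self.altitude_agl, self.gsd_cm)


@dataclass(frozen=True)
class Distractor:
    kind: str
    bbox: BoundingBox


@dataclass
class DistractorSet:
    """Non-animal objects present in the raster; never part of the reference."""

    mosaic_id: str
    items: list[Distractor] = field(default_factory=list)

    def __len__(self):
        return len(self.items)

    def __iter__(self):
        return iter(self.items)


class Scene(NamedTuple):
    raster: np.ndarray
    truth: AnnotationSet
    distractors: DistractorSet
    meta: MosaicMeta


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length *sigma*."""
    n = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return n / max(n.std(), 1e-9)


def _render_background(rng: np.random.Generator, width: int, height: int) -> np.ndarray:
    shape = (height, width)
    img = 95.0 + 22.0 * _smooth_noise(rng, shape, 45)
    img += 10.0 * _smooth_noise(rng, shape, 8)
    img += 5.0 * _smooth_noise(rng, shape, 1.5)
    # darker shrub/water patches where a slow field runs high
    patches = _smooth_noise(rng, shape, 70)
    img -= 35.0 / (1.0 + np.exp(-(patches - 1.1) * 4.0))
    return img


def _sprite(rng: np.random.Generator, length_px: float, width_px: float,
            angle: float, intensity: float, texture: float = 8.0
            ) -> tuple[np.ndarray, np.ndarray]:
    """Render an elongated soft-edged blob; returns (intensity, alpha) patches."""
    a, b = length_px / 2.0, width_px / 2.0
    half = int(math.ceil(max(a, b))) + 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    u = math.cos(angle) * xx + math.sin(angle) * yy
    v = -math.sin(angle) * xx + math.cos(angle) * yy
    r2 = (u / a) ** 2 + (v / b) ** 2
    alpha = np.clip((1.0 - r2) * 3.0, 0.0, 1.0)
    body = intensity + 35.0 * np.clip(1.0 - r2, 0.0, 1.0)
    body += texture * ndimage.gaussian_filter(
        rng.standard_normal(alpha.shape), 1.0)
    return body, alpha


def _composite(img: np.ndarray, body: np.ndarray, alpha: np.ndarray,
               cx: int, cy: int) -> Optional[BoundingBox]:
    """Alpha-blend a patch centered at (cx, cy); returns the tight box of its pixels."""
    h, w = alpha.shape
    y0, x0 = cy - h // 2, cx - w // 2
    sy0, sx0 = max(0, -y0), max(0, -x0)
    iy0, ix0 = max(0, y0), max(0, x0)
    iy1 = min(img.shape[0], y0 + h)
    ix1 = min(img.shape[1], x0 + w)
    if iy1 <= iy0 or ix1 <= ix0:
        return None
    sub_a = alpha[sy0:sy0 + (iy1 - iy0), sx0:sx0 + (ix1 - ix0)]
    sub_b = body[sy0:sy0 + (iy1 - iy0), sx0:sx0 + (ix1 - ix0)]
    img[iy0:iy1, ix0:ix1] = (img[iy0:iy1, ix0:ix1] * (1 - sub_a) + sub_b * sub_a)
    visible = sub_a > 0.05
    if not visible.any():
        return None
    rows = np.flatnonzero(visible.any(axis=1))
    cols = np.flatnonzero(visible.any(axis=0))
    return BoundingBox(ix0 + int(cols[0]), iy0 + int(rows[0]),
                       ix0 + int(cols[-1]) + 1, iy0 + int(rows[-1]) + 1)


def _place_centers(rng: np.random.Generator, n: int, width: int, height: int,
                   margin: int, min_sep: float, taken: list[tuple[int, int]],
                   max_tries_each: int = 300) -> list[tuple[int, int]]:
    placed: list[tuple[int, int]] = []
    for _ in range(n):
        for _try in range(max_tries_each):
            cx = int(rng.integers(margin, width - margin))
            cy = int(rng.integers(margin, height - margin))
            if all((cx - tx) ** 2 + (cy - ty) ** 2 >= min_sep ** 2
                   for tx, ty in taken):
                taken.append((cx, cy))
                placed.append((cx, cy))
                break
        else:
            raise CapacityError(
                f"could not place object {len(placed) + 1} of {n} at "
                f"min separation {min_sep}px", achieved=len(placed),
            )
    return placed


def generate_scene(spec: SceneSpec) -> Scene:
    """Render a synthetic mosaic with ground truth; deterministic given ``spec.seed``.

    Returns the raster (uint8 grayscale, shape ``(height, width)``), the truth
    :class:`~mosaicount.annotations.AnnotationSet` (boxes tightly enclosing
    each rendered sprite), the rendered-but-separate distractors, and the
    mosaic metadata.

    Raises :class:`~mosaicount.errors.CapacityError` when the requested counts
    cannot be placed at ``min_separation_px`` within bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    img = _render_background(rng, spec.width, spec.height)
    ppm = spec.px_per_m
    margin = int(math.ceil(spec.adult_length_m[1] * ppm / 2)) + 6

    taken: list[tuple[int, int]] = []
    n_animals = spec.n_adult + spec.n_calf + spec.n_ghost
    centers = _place_centers(rng, n_animals, spec.width, spec.height,
                             margin, spec.min_separation_px, taken)
    annotations: list[Annotation] = []
    labels = ([Label.ADULT] * spec.n_adult + [Label.CALF] * spec.n_calf
              + [Label.GHOST] * spec.n_ghost)
    for (cx, cy), label in zip(centers, labels):
        length = rng.uniform(*spec.adult_length_m) * ppm
        if label is Label.CALF:
            length *= rng.uniform(*spec.calf_scale)
        width_px = length * rng.uniform(0.38, 0.5)
        angle = rng.uniform(0, math.pi)
        intensity = rng.uniform(175, 205)
        body, alpha = _sprite(rng, length, width_px, angle, intensity)
        if label is Label.GHOST:
            sigma = rng.uniform(*spec.ghost_blur_sigma_px)
            g_alpha = rng.uniform(*spec.ghost_alpha)
            body = ndimage.gaussian_filter(body, sigma)
            alpha = ndimage.gaussian_filter(alpha, sigma) * g_alpha
        bbox = _composite(img, body, alpha, cx, cy)
        if bbox is None:  # sprite fell entirely off-canvas; margins prevent this
            continue
        annotations.append(Annotation(bbox, label))

    distractors: list[Distractor] = []
    kinds = (["rock"] * spec.n_rock + ["bird"] * spec.n_bird
             + ["trunk"] * spec.n_trunk)
    d_centers = _place_centers(rng, len(kinds), spec.width, spec.height,
                               margin, spec.min_separation_px, taken)
    for (cx, cy), kind in zip(d_centers, kinds):
        if kind == "rock":
            size = rng.uniform(0.5, 1.2) * ppm
            body, alpha = _sprite(rng, size, size * rng.uniform(0.7, 1.0),
                                  rng.uniform(0, math.pi), rng.uniform(125, 150),
                                  texture=12.0)
        elif kind == "bird":
            size = rng.uniform(0.25, 0.45) * ppm
            body, alpha = _sprite(rng, size, size * rng.uniform(0.6, 0.9),
                                  rng.uniform(0, math.pi), rng.uniform(215, 240))
        else:  # trunk: thin, dark, elongated
            length = rng.uniform(1.2, 3.0) * ppm
            body, alpha = _sprite(rng, length, length * rng.uniform(0.08, 0.15),
                                  rng.uniform(0, math.pi), rng.uniform(35, 60))
        bbox = _composite(img, body, alpha, cx, cy)
        if bbox is not None:
            distractors.append(Distractor(kind, bbox))

    raster = np.clip(img, 0, 255).astype(np.uint8)
    truth = AnnotationSet(spec.mosaic_id, "truth", annotations)
    return Scene(raster, truth, DistractorSet(spec.mosaic_id, distractors),
                 spec.meta())


def _identity_confusion(miss_prob: dict[Label, float]) -> dict[Label, dict[Label, float]]:
    return {y: {x: (1.0 - miss_prob.get(y, 0.0) if x is y else 0.0)
                for x in LABELS} for y in LABELS}


@dataclass
class ObserverModel:
    """Stochastic error model for a simulated annotator.

    For each true animal of class ``y`` the annotator misses it with
    ``miss_prob[y]``, otherwise labels it ``x`` with ``confusion[y][x]``;
    the miss probability and the confusion row must sum to 1.  Box corners are
    jittered with a normal of SD ``bbox_jitter_sd_px``.  ``object_fp_rate[x]``
    is the expected number of spurious class-``x`` annotations per 100
    distractor objects (0 for human observers, who do not annotate rocks or
    birds as animals; detector-like annotators may set it > 0).  If
    ``confidence_beta`` is set, every emitted annotation carries a Beta(a, b)
    confidence, as detector output does.
    """

    miss_prob: dict[Label, float] = field(default_factory=dict)
    confusion: Optional[dict[Label, dict[Label, float]]] = None
    bbox_jitter_sd_px: float = 0.0
    object_fp_rate: dict[Label, float] = field(default_factory=dict)
    confidence_beta: Optional[tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self):
        self.miss_prob = {Label(k): float(v) for k, v in self.miss_prob.items()}
        if self.confusion is None:
            self.confusion = _identity_confusion(self.miss_prob)
        else:
            self.confusion = {
                Label(y): {Label(x): float(p) for x, p in row.items()}
                for y, row in self.confusion.items()
            }
        self.object_fp_rate = {Label(k): float(v)
                               for k, v in self.object_fp_rate.items()}
        for y in LABELS:
            miss = self.miss_prob.get(y, 0.0)
            row = self.confusion.get(y, {})
            probs = [miss, *row.values()]
            if any(p < 0 or p > 1 for p in probs):
                raise ObserverModelError(f"probabilities for {y.value} outside [0,1]")
            total = miss + sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ObserverModelError(
                    f"miss + confusion row for {y.value} sums to {total}, not 1"
                )


def simulate_observer(truth: AnnotationSet, distractors: DistractorSet,
                      model: ObserverModel,
                      source_id: str = "observer",
                      bounds: Optional[tuple[int, int]] = None) -> AnnotationSet:
    """Apply an :class:`ObserverModel` to ground truth; deterministic given its seed.

    *bounds* (width, height), when given, clips jittered boxes in-bounds while
    preserving positive area.
    """
    rng = np.random.default_rng(model.seed)

    def _jitter(bbox: BoundingBox) -> BoundingBox:
        if model.bbox_jitter_sd_px <= 0:
            return bbox
        d = rng.normal(0.0, model.bbox_jitter_sd_px, size=4)
        x0 = bbox.x0 + int(round(d[0]))
        y0 = bbox.y0 + int(round(d[1]))
        x1 = bbox.x1 + int(round(d[2]))
        y1 = bbox.y1 + int(round(d[3]))
        if bounds is not None:
            w, h = bounds
            x0, x1 = max(0, min(x0, w - 1)), max(1, min(x1, w))
            y0, y1 = max(0, min(y0, h - 1)), max(1, min(y1, h))
        else:
            x0, y0 = max(0, x0), max(0, y0)
        if x1 <= x0:
            x1 = x0 + 1
        if y1 <= y0:
            y1 = y0 + 1
        return BoundingBox(x0, y0, x1, y1)

    def _confidence() -> Optional[float]:
        if model.confidence_beta is None:
            return None
        a, b = model.confidence_beta
        return float(rng.beta(a, b))

    out: list[Annotation] = []
    for ann in truth:
        y = ann.label
        miss = model.miss_prob.get(y, 0.0)
        u = rng.random()
        if u < miss:
            continue
        acc = miss
        chosen = None
        for x in LABELS:
            acc += model.confusion[y].get(x, 0.0)
            if u < acc:
                chosen = x
                break
        if chosen is None:  # numerical guard; rows sum to 1
            chosen = y
        out.append(Annotation(_jitter(ann.bbox), chosen, _confidence()))

    for dis in distractors:
        for x in LABELS:
            rate = model.object_fp_rate.get(x, 0.0)
            if rate > 0 and rng.random() < rate / 100.0:
                out.append(Annotation(_jitter(dis.bbox), x, _confidence()))

    return AnnotationSet(truth.mosaic_id, source_id, out)


# Observer-pool error levels used by the fixture suite: a zero-error
# expert-like reference, moderately error-prone naive observers, and a
# detector-like annotator that also mistakes distractor objects for animals.
NAIVE_OBSERVER_PARAMS = dict(
    miss_prob={Label.ADULT: 0.05, Label.CALF: 0.07, Label.GHOST: 0.20},
    confusion={
        Label.ADULT: {Label.ADULT: 0.84, Label.CALF: 0.05, Label.GHOST: 0.06},
        Label.CALF: {Label.ADULT: 0.04, Label.CALF: 0.87, Label.GHOST: 0.02},
        Label.GHOST: {Label.ADULT: 0.04, Label.CALF: 0.02, Label.GHOST: 0.74},
    },
    bbox_jitter_sd_px=2.0,
)

DETECTOR_OBSERVER_PARAMS = dict(
    miss_prob={Label.ADULT: 0.02, Label.CALF: 0.05, Label.GHOST: 0.45},
    confusion={
        Label.ADULT: {Label.ADULT: 0.93, Label.CALF: 0.03, Label.GHOST: 0.02},
        Label.CALF: {Label.ADULT: 0.03, Label.CALF: 0.90, Label.GHOST: 0.02},
        Label.GHOST: {Label.ADULT: 0.10, Label.CALF: 0.02, Label.GHOST: 0.43},
    },
    bbox_jitter_sd_px=1.5,
    object_fp_rate={Label.ADULT: 15.0, Label.CALF: 3.0, Label.GHOST: 2.0},
    confidence_beta=(6.0, 2.0),
)


def _plain(obj):
    """Recursively convert to YAML-safe plain types."""
    if isinstance(obj, dict):
        return {(_plain(k)): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, Label):
        return obj.value
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def build_fixture_suite(out_dir, seed: int) -> tuple[Path, dict]:
    """Emit a full study-shaped fixture directory; byte-reproducible given *seed*.

    Four scenes (two per GSD preset, echoing two mosaics per flight altitude),
    each with the rendered mosaic PNG, metadata sidecar, ground truth, an
    expert-like zero-error annotation set, five naive-like observers, a
    detector-like set with confidences, and the distractor inventory.  A
    manifest records every generative parameter.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "scenes": []}

    scene_defs = [
        ("mosaic-75a", 2.4, 60, 25, 15),
        ("mosaic-75b", 2.4, 75, 25, 20),
        ("mosaic-120a", 3.7, 60, 25, 15),
        ("mosaic-120b", 3.7, 75, 25, 20),
    ]
    for mosaic_id, gsd, n_adult, n_calf, n_ghost in scene_defs:
        spec = SceneSpec(
            mosaic_id=mosaic_id, gsd_cm=gsd,
            n_adult=n_adult, n_calf=n_calf, n_ghost=n_ghost,
            seed=int(master.integers(0, 2**31 - 1)),
        )
        scene = generate_scene(spec)
        scene_dir = out_dir / mosaic_id
        scene_dir.mkdir(exist_ok=True)
        iio.imwrite(scene_dir / "mosaic.png", scene.raster)
        scene.meta.write(scene_dir / "meta.yaml")
        write_annotations(scene.truth, scene_dir / "truth.csv")

        sources: dict[str, dict] = {}
        expert_model = ObserverModel(seed=int(master.integers(0, 2**31 - 1)))
        expert = simulate_observer(scene.truth, scene.distractors, expert_model,
                                   "expert", (spec.width, spec.height))
        write_annotations(expert, scene_dir / "expert.csv")
        sources["expert"] = _plain(asdict(expert_model))

        for k in range(1, 6):
            model = ObserverModel(**NAIVE_OBSERVER_PARAMS,
                                  seed=int(master.integers(0, 2**31 - 1)))
            naive = simulate_observer(scene.truth, scene.distractors, model,
                                      f"naive-{k}", (spec.width, spec.height))
            write_annotations(naive, scene_dir / f"naive-{k}.csv")
            sources[f"naive-{k}"] = _plain(asdict(model))

        det_model = ObserverModel(**DETECTOR_OBSERVER_PARAMS,
                                  seed=int(master.integers(0, 2**31 - 1)))
        detector = simulate_observer(scene.truth, scene.distractors, det_model,
                                     "detector", (spec.width, spec.height))
        write_annotations(detector, scene_dir / "detector.csv")
        sources["detector"] = _plain(asdict(det_model))

        with (scene_dir / "distractors.csv").open("w") as fh:
            fh.write("mosaic_id,kind,x0,y0,x1,y1\n")
            for d in scene.distractors:
                fh.write(f"{mosaic_id},{d.kind},{d.bbox.x0},{d.bbox.y0},"
                         f"{d.bbox.x1},{d.bbox.y1}\n")

        manifest["scenes"].append({
            "mosaic_id": mosaic_id,
            "spec": _plain(asdict(spec)),
            "sources": sources,
            "n_truth": len(scene.truth),
            "n_distractors": len(scene.distractors),
        })

    (out_dir / "manifest.yaml").write_text(
        yaml.safe_dump(_plain(manifest), sort_keys=False))
    return out_dir, manifest
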