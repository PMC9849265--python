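"""Labeled bounding-box annotations on orthomosaics.

Observers (or a detector) mark each animal on a mosaic with an axis-aligned
rectangle and one of three labels: ``adult``, ``calf``, or ``ghost``.  A
"ghost" is the blurred, semi-transparent imprint left by an animal that moved
between the overlapping photos a mosaic is stitched from; it is counted as its
own class so that mosaicking artifacts are accounted for rather than silently
inflating or deflating counts.

Coordinates are integer pixels, origin at the mosaic's top-left, half-open
intervals ``[x0, x1) x [y0, y1)`` so that ``width = x1 - x0`` and tile
arithmetic is exact.  Annotation files are headered CSV, one box per row::

    mosaic_id,label,x0,y0,x1,y1,confidence

with ``confidence`` blank for human annotations.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import yaml

from .errors import (
    AnnotationParseError,
    BoundsError,
    VocabularyError,
)

__all__ = [
    "Label",
    "BoundingBox",
    "Annotation",
    "AnnotationSet",
    "MosaicMeta",
    "read_annotations",
    "write_annotations",
    "box_iou",
]


class Label(str, enum.Enum):
    """The closed three-class evaluation vocabulary."""

    ADULT = "adult"
    CALF = "calf"
    GHOST = "ghost"

    @classmethod
    def normalize(cls, raw: str) -> "Label":
        """Map a raw label string to the vocabulary.

        Accepts the bare class name or the full field phrase (e.g.
        ``"adult caribou"``), case-insensitively.  Anything else raises
        :class:`~mosaicount.errors.VocabularyError`.
        """
        key = raw.strip().lower()
        if key.endswith(" caribou"):
            key = key[: -len(" caribou")]
        try:
            return cls(key)
        except ValueError:
            raise VocabularyError(
                f"unknown label {raw!r}; expected one of "
                f"{[m.value for m in cls]} (optionally suffixed ' caribou')"
            ) from None


LABELS: tuple[Label, ...] = (Label.ADULT, Label.CALF, Label.GHOST)


@dataclass(frozen=True, order=True)
class BoundingBox:
    """Axis-aligned integer pixel rectangle, half-open, origin top-left."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        for name in ("x0", "y0", "x1", "y1"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"negative origin: {self}")
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"box must have positive area: {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def translate(self, dx: int, dy: int) -> "BoundingBox":
        return BoundingBox(self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy)

    def intersection_area(self, other: "BoundingBox") -> int:
        w = min(self.x1, other.x1) - max(self.x0, other.x0)
        h = min(self.y1, other.y1) - max(self.y0, other.y0)
        return w * h if (w > 0 and h > 0) else 0

    def contains_point(self, x: int, y: int) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def check_within(self, width: int, height: int) -> None:
        if self.x1 > width or self.y1 > height:
            raise BoundsError(
                f"box {self} exceeds mosaic bounds {width}x{height}"
            )


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes under the half-open convention.

    Symmetric, in [0, 1]; disjoint boxes give 0.0 and identical boxes 1.0.
    """
    inter = a.intersection_area(b)
    if inter == 0:
        return 0.0
    union = a.area + b.area - inter
    return inter / union


@dataclass(frozen=True)
class Annotation:
    """One labeled box; ``confidence`` present only for detector output."""

    bbox: BoundingBox
    label: Label
    confidence: Optional[float] = None

    def __post_init__(self):
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence outside [0,1]: {self.confidence}")


@dataclass
class AnnotationSet:
    """Ordered annotations from one source (observer / model / truth) on one mosaic."""

    mosaic_id: str
    source_id: str
    annotations: list[Annotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self) -> Iterator[Annotation]:
        return iter(self.annotations)

    def __getitem__(self, i) -> Annotation:
        return self.annotations[i]

    def counts_by_label(self) -> dict[Label, int]:
        out = {lab: 0 for lab in LABELS}
        for a in self.annotations:
            out[a.label] += 1
        return out

    def check_bounds(self, meta: "MosaicMeta") -> None:
        """Raise BoundsError if any box exceeds the mosaic dimensions."""
        for a in self.annotations:
            a.bbox.check_within(meta.width, meta.height)

    def with_annotations(self, annotations: Iterable[Annotation]) -> "AnnotationSet":
        return AnnotationSet(self.mosaic_id, self.source_id, list(annotations))


@dataclass(frozen=True)
class MosaicMeta:
    """Mosaic dimensions and acquisition geometry.

    ``gsd_cm`` is the ground sampling distance: the real-world size of one
    pixel in centimeters (2.4 cm at 75 m above ground, 3.7 cm at 120 m for
    the fixed-wing surveys this pipeline was designed around).
    """

    mosaic_id: str
    width: int
    height: int
    altitude_agl: Optional[float] = None
    gsd_cm: Optional[float] = None

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("mosaic dimensions must be positive")
        if self.gsd_cm is not None and self.gsd_cm <= 0:
            raise ValueError("gsd_cm must be positive")

    def to_dict(self) -> dict:
        return {
            "mosaic_id": self.mosaic_id,
            "width": self.width,
            "height": self.height,
            "altitude_agl": self.altitude_agl,
            "gsd_cm": self.gsd_cm,
        }

    def write(self, path) -> Path:
        """Write a YAML/JSON sidecar (format chosen by file extension)."""
        path = Path(path)
        data = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path

    @classmethod
    def read(cls, path) -> "MosaicMeta":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)


_CSV_HEADER = ["mosaic_id", "label", "x0", "y0", "x1", "y1", "confidence"]


def read_annotations(path, meta: Optional[MosaicMeta] = None,
                     source_id: Optional[str] = None) -> AnnotationSet:
    """Read an annotation CSV into an :class:`AnnotationSet`.

    Rows are returned in file order.  Labels are normalized to the three-value
    vocabulary (full "... caribou" phrases accepted).  If *meta* is given,
    every box is checked against the mosaic bounds.

    Parameters
    ----------
    path : file path
    meta : optional MosaicMeta for bounds checking
    source_id : identity recorded on the set; defaults to the file stem

    Raises
    ------
    AnnotationParseError, VocabularyError, BoundsError
    """
    path = Path(path)
    if source_id is None:
        source_id = path.stem
    annotations: list[Annotation] = []
    mosaic_id = meta.mosaic_id if meta is not None else ""
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise AnnotationParseError(path, 1, "empty file (missing header)")
        if [h.strip() for h in header] != _CSV_HEADER:
            raise AnnotationParseError(
                path, 1, f"bad header {header!r}; expected {_CSV_HEADER}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(_CSV_HEADER):
                raise AnnotationParseError(
                    path, line_no, f"expected {len(_CSV_HEADER)} fields, got {len(row)}"
                )
            row_mosaic, raw_label, *coords, raw_conf = row
            row_mosaic = row_mosaic.strip()
            if meta is not None and row_mosaic != meta.mosaic_id:
                raise AnnotationParseError(
                    path, line_no,
                    f"mosaic_id {row_mosaic!r} does not match metadata "
                    f"{meta.mosaic_id!r}",
                )
            if not mosaic_id:
                mosaic_id = row_mosaic
            elif row_mosaic != mosaic_id:
                raise AnnotationParseError(
                    path, line_no,
                    f"mixed mosaic ids in one file: {mosaic_id!r} vs {row_mosaic!r}",
                )
            label = Label.normalize(raw_label)
            try:
                x0, y0, x1, y1 = (int(c) for c in coords)
            except ValueError:
                raise AnnotationParseError(
                    path, line_no, f"non-integer coordinates {coords!r}"
                ) from None
            try:
                bbox = BoundingBox(x0, y0, x1, y1)
            except ValueError as exc:
                raise AnnotationParseError(path, line_no, str(exc)) from None
            conf = None
            if raw_conf.strip():
                try:
                    conf = float(raw_conf)
                except ValueError:
                    raise AnnotationParseError(
                        path, line_no, f"bad confidence {raw_conf!r}"
                    ) from None
            annotations.append(Annotation(bbox, label, conf))
    aset = AnnotationSet(mosaic_id, source_id, annotations)
    if meta is not None:
        aset.check_bounds(meta)
    return aset


def write_annotations(aset: AnnotationSet, path) -> Path:
    """Write *aset* as annotation CSV; reading it back reproduces the set.

    Confidences are written with 6 decimals; order and labels are preserved.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for a in aset.annotations:
            conf = "" if a.confidence is None else f"{a.confidence:.6f}"
            writer.writerow(
                [aset.mosaic_id, a.label.value,
                 a.bbox.x0, a.bbox.y0, a.bbox.x1, a.bbox.y1, conf]
            )
    return path
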