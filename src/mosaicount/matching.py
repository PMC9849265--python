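"""One-to-one matching of detections to reference annotations.

Evaluation treats the experienced observer's annotations as ground truth: a
compared set (model or naive observer) is matched box-by-box against the
reference, and the correspondences are turned into true-positive /
false-positive / false-negative tallies.

Matching is geometric and greedy: all cross pairs with IoU at or above the
threshold are considered in order of descending IoU (ties broken by smaller
center distance, then lower reference index, then lower predicted index), and
a pair is accepted only if both members are still unmatched.  Labels are
ignored during matching by default — whether a matched pair *agrees* on the
class is settled afterwards in :func:`derive_counts`, where a label mismatch
counts as a false positive for the predicted class and a false negative for
the reference class (a calf annotated as an adult is both a spurious "adult"
and a missed "calf"), while still being a pooled species-level true positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import Annotation, AnnotationSet, Label, LABELS
from .errors import FrameError

__all__ = [
    "MatchResult",
    "EvalCounts",
    "ConfusionTable",
    "match_sets",
    "derive_counts",
    "iou_matrix",
]

POOLED = "species"

#: confusion-table row for spurious predictions with no reference counterpart
OBJECT = "object"
#: confusion-table column for reference animals nobody predicted
MISSED = "missed"


@dataclass(frozen=True)
class MatchResult:
    """One-to-one correspondences: (reference idx, predicted idx, IoU) plus leftovers."""

    pairs: tuple[tuple[int, int, float], ...]
    unmatched_reference: tuple[int, ...]
    unmatched_predicted: tuple[int, ...]
    iou_threshold: float


@dataclass
class EvalCounts:
    """TP/FP/FN tallies per class and pooled over classes ("species")."""

    counts: dict[str, dict[str, int]]

    def __getitem__(self, key: str) -> dict[str, int]:
        return self.counts[key]

    @property
    def pooled(self) -> dict[str, int]:
        return self.counts[POOLED]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts).T[["tp", "fp", "fn"]]


@dataclass
class ConfusionTable:
    """Cross-class tallies: reference class (rows) vs predicted outcome (columns).

    Rows are the three animal classes plus ``object`` (a spurious prediction
    with no reference animal under it); columns are the three classes plus
    ``missed``.  Diagonal entries equal the per-class true positives.
    """

    table: dict[str, dict[str, int]] = field(default_factory=lambda: {
        row: {col: 0 for col in [*(l.value for l in LABELS), MISSED]}
        for row in [*(l.value for l in LABELS), OBJECT]
    })

    def __getitem__(self, key: tuple[str, str]) -> int:
        row, col = key
        return self.table[row][col]

    def add(self, row: str, col: str, n: int = 1) -> None:
        self.table[row][col] += n

    def row_total(self, row: str) -> int:
        return sum(self.table[row].values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.table).T


def iou_matrix(ref: AnnotationSet, pred: AnnotationSet) -> np.ndarray:
    """Pairwise IoU between all reference and predicted boxes, shape (n_ref, n_pred)."""
    if len(ref) == 0 or len(pred) == 0:
        return np.zeros((len(ref), len(pred)))
    a = np.array([[b.bbox.x0, b.bbox.y0, b.bbox.x1, b.bbox.y1] for b in ref], float)
    b = np.array([[b.bbox.x0, b.bbox.y0, b.bbox.x1, b.bbox.y1] for b in pred], float)
    ix0 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy0 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix1 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix1 - ix0, 0, None) * np.clip(iy1 - iy0, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return inter / union


def match_sets(reference: AnnotationSet, predicted: AnnotationSet,
               iou_threshold: float = 0.3,
               class_agnostic: bool = True) -> MatchResult:
    """Greedy one-to-one matching of *predicted* boxes to *reference* boxes.

    Candidate pairs (IoU >= threshold; same label only if not class-agnostic)
    are accepted in descending-IoU order, each index used at most once.

    Raises :class:`~mosaicount.errors.FrameError` if the sets name different
    mosaics.
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise ValueError(f"iou_threshold must be in (0,1], got {iou_threshold}")
    if (reference.mosaic_id and predicted.mosaic_id
            and reference.mosaic_id != predicted.mosaic_id):
        raise FrameError(
            f"cannot match across mosaics: {reference.mosaic_id!r} vs "
            f"{predicted.mosaic_id!r}"
        )
    ious = iou_matrix(reference, predicted)
    cand_r, cand_p = np.nonzero(ious >= iou_threshold)
    if not class_agnostic and cand_r.size:
        same = np.array([reference[r].label == predicted[p].label
                         for r, p in zip(cand_r, cand_p)])
        cand_r, cand_p = cand_r[same], cand_p[same]

    if cand_r.size:
        centers_r = np.array([reference[r].bbox.center for r in cand_r])
        centers_p = np.array([predicted[p].bbox.center for p in cand_p])
        cdist = np.hypot(*(centers_r - centers_p).T)
        cand_iou = ious[cand_r, cand_p]
        # lexsort: primary key last -> IoU desc, then center dist, ref idx, pred idx
        order = np.lexsort((cand_p, cand_r, cdist, -cand_iou))
    else:
        order = np.array([], dtype=int)

    pairs: list[tuple[int, int, float]] = []
    used_r: set[int] = set()
    used_p: set[int] = set()
    for k in order:
        r, p = int(cand_r[k]), int(cand_p[k])
        if r in used_r or p in used_p:
            continue
        used_r.add(r)
        used_p.add(p)
        pairs.append((r, p, float(ious[r, p])))
    return MatchResult(
        pairs=tuple(pairs),
        unmatched_reference=tuple(r for r in range(len(reference)) if r not in used_r),
        unmatched_predicted=tuple(p for p in range(len(predicted)) if p not in used_p),
        iou_threshold=iou_threshold,
    )


def derive_counts(match: MatchResult, reference: AnnotationSet,
                  predicted: AnnotationSet) -> tuple[EvalCounts, ConfusionTable]:
    """Turn a class-agnostic match into per-class and pooled TP/FP/FN tallies.

    Pooled ("species") level: every matched pair is a true positive, every
    unmatched prediction a false positive, every unmatched reference a false
    negative.  Per class ``c``: a pair with both labels ``c`` is a true
    positive; a label-mismatched pair adds a false positive to the predicted
    class and a false negative to the reference class; unmatched boxes add to
    their own class's FP (predictions) or FN (references).

    The confusion table records the same events cross-classified: pair label
    combinations on the class-by-class block, unmatched predictions in the
    ``object`` row, unmatched references in the ``missed`` column.
    """
    counts = {key: {"tp": 0, "fp": 0, "fn": 0}
              for key in [POOLED, *(l.value for l in LABELS)]}
    confusion = ConfusionTable()

    for r, p, _iou in match.pairs:
        ref_lab = reference[r].label.value
        pred_lab = predicted[p].label.value
        counts[POOLED]["tp"] += 1
        confusion.add(ref_lab, pred_lab)
        if ref_lab == pred_lab:
            counts[ref_lab]["tp"] += 1
        else:
            counts[pred_lab]["fp"] += 1
            counts[ref_lab]["fn"] += 1
    for p in match.unmatched_predicted:
        lab = predicted[p].label.value
        counts[POOLED]["fp"] += 1
        counts[lab]["fp"] += 1
        confusion.add(OBJECT, lab)
    for r in match.unmatched_reference:
        lab = reference[r].label.value
        counts[POOLED]["fn"] += 1
        counts[lab]["fn"] += 1
        confusion.add(lab, MISSED)
    return EvalCounts(counts), confusion
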