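"""Multi-source comparison against a designated reference observer.

The study design this mirrors has one experienced observer (treated as exhaustive
and correct), a group of naive observers, and a detector, all annotating the
same mosaics.  Each source is evaluated against the reference with the
matching + metrics stack; naive observers are additionally pooled into
mean +/- SD summaries, and per-tile count vectors support Pearson-correlation
reports with 1:1 scatter data.

Evaluation can run on the whole mosaic or be restricted to a held-out set of
test tiles (the scope a detector trained on the other tiles is scored on).
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, Label, LABELS
from .errors import FrameError, InputError, UndefinedMetricError
from .matching import POOLED, ConfusionTable, derive_counts, match_sets
from .metrics import (
    accuracy,
    misclass_proportion,
    missing_proportion,
    pct_diff,
    per_tile_correlation,
    precision,
    recall,
    round_half_up,
)
from .tiling import TileGrid, assign_to_tiles

__all__ = [
    "ClassStats",
    "SourceSummary",
    "PooledSummary",
    "evaluate_source",
    "pool_observers",
    "per_tile_counts",
    "correlation_report",
    "plot_correlation",
    "results_table",
    "misclassification_table",
]

_METRIC_FIELDS = ("accuracy", "precision", "recall", "pct_diff", "missing_proportion")
_COUNT_FIELDS = ("raw_count", "ref_count", "tp", "fp", "fn")


@dataclass
class ClassStats:
    """Counts and derived metrics for one class (or the pooled species level)."""

    raw_count: int
    ref_count: int
    tp: int
    fp: int
    fn: int
    accuracy: Optional[float] = None
    precision: Optional[float] = None
    recall: Optional[float] = None
    pct_diff: Optional[float] = None
    missing_proportion: Optional[float] = None


def _safe(fn, *args):
    try:
        return fn(*args)
    except UndefinedMetricError:
        return None


@dataclass
class SourceSummary:
    """One source evaluated against the reference on one mosaic."""

    source_id: str
    mosaic_id: str
    scope: str
    stats: dict[str, ClassStats]
    confusion: ConfusionTable
    per_tile: Optional[dict[str, np.ndarray]] = None
    processing_time_min: Optional[float] = None


@dataclass
class PooledSummary:
    """Mean +/- sample-SD over a pool of observers, per class.

    ``metrics_of_mean_counts`` recomputes accuracy/precision/recall/pct_diff
    from the pooled *mean* TP/FP/FN/raw counts (the convention of an
    "all observers" table row); ``mean``/``sd`` carry the per-field averages,
    including the mean of the per-observer metrics.
    """

    mosaic_id: str
    n_observers: int
    mean: dict[str, ClassStats]
    sd: dict[str, ClassStats]
    metrics_of_mean_counts: dict[str, ClassStats]


def per_tile_counts(grid: TileGrid, aset: AnnotationSet,
                    label: Optional[Label] = None) -> np.ndarray:
    """Count annotations owned by each tile, in the grid's row-major tile order."""
    owned = assign_to_tiles(grid, aset)
    out = np.zeros(grid.n_tiles, dtype=int)
    for pos, tile in enumerate(grid.tiles()):
        tset = owned.get(tile.index)
        if tset is None:
            continue
        out[pos] = (len(tset) if label is None
                    else sum(1 for a in tset if a.label == label))
    return out


def _restrict_to_tiles(grid: TileGrid, aset: AnnotationSet,
                       tile_indices: set[tuple[int, int]]) -> AnnotationSet:
    kept = [a for a in aset
            if grid.owner_index(a.bbox.x0, a.bbox.y0) in tile_indices]
    return aset.with_annotations(kept)


def evaluate_source(reference: AnnotationSet,
                    source: AnnotationSet,
                    grid: Optional[TileGrid] = None,
                    scope: Literal["whole-mosaic", "test-tiles"] = "whole-mosaic",
                    test_tiles: Optional[Iterable] = None,
                    iou_threshold: float = 0.3,
                    pct_diff_denominator: Literal["reference", "test"] = "reference",
                    processing_time_min: Optional[float] = None) -> SourceSummary:
    """Evaluate one source against the reference observer.

    Runs class-agnostic matching, derives TP/FP/FN and confusion tallies, and
    computes the metric set per class and pooled.  With a *grid*, per-tile
    count vectors are retained for correlation reports; with
    ``scope="test-tiles"`` both sets are first restricted to annotations owned
    by the supplied test tiles.
    """
    if (reference.mosaic_id and source.mosaic_id
            and reference.mosaic_id != source.mosaic_id):
        raise FrameError(
            f"reference is on mosaic {reference.mosaic_id!r}, source on "
            f"{source.mosaic_id!r}"
        )
    if scope == "test-tiles":
        if grid is None or test_tiles is None:
            raise InputError("test-tiles scope requires a grid and a tile split")
        indices = {t[1] if isinstance(t[0], str) else tuple(t) for t in test_tiles}
        reference = _restrict_to_tiles(grid, reference, indices)
        source = _restrict_to_tiles(grid, source, indices)
    elif scope != "whole-mosaic":
        raise InputError(f"unknown scope {scope!r}")

    match = match_sets(reference, source, iou_threshold=iou_threshold,
                       class_agnostic=True)
    counts, confusion = derive_counts(match, reference, source)

    ref_by_label = reference.counts_by_label()
    src_by_label = source.counts_by_label()
    stats: dict[str, ClassStats] = {}
    for key in [POOLED, *(l.value for l in LABELS)]:
        c = counts[key]
        if key == POOLED:
            raw, ref_n = len(source), len(reference)
        else:
            raw, ref_n = src_by_label[Label(key)], ref_by_label[Label(key)]
        stats[key] = ClassStats(
            raw_count=raw, ref_count=ref_n,
            tp=c["tp"], fp=c["fp"], fn=c["fn"],
            accuracy=_safe(accuracy, c["tp"], c["fp"], c["fn"]),
            precision=_safe(precision, c["tp"], c["fp"]),
            recall=_safe(recall, c["tp"], c["fn"]),
            pct_diff=_safe(pct_diff, raw, ref_n, pct_diff_denominator),
            missing_proportion=_safe(missing_proportion, c["fn"], c["tp"]),
        )

    per_tile = None
    if grid is not None:
        per_tile = {POOLED: per_tile_counts(grid, source)}
        for lab in LABELS:
            per_tile[lab.value] = per_tile_counts(grid, source, lab)

    return SourceSummary(
        source_id=source.source_id,
        mosaic_id=source.mosaic_id or reference.mosaic_id,
        scope=scope,
        stats=stats,
        confusion=confusion,
        per_tile=per_tile,
        processing_time_min=processing_time_min,
    )


def pool_observers(summaries: Sequence[SourceSummary]) -> PooledSummary:
    """Pool several observers' summaries into mean +/- sample SD per cell.

    Sample SD uses ddof=1; a single-observer pool reports SD 0.  Metric cells
    are additionally recomputed from the pooled mean counts
    (``metrics_of_mean_counts``), the convention of aggregate table rows.
    Pooling is permutation-invariant.
    """
    if not summaries:
        raise InputError("cannot pool an empty list of observer summaries")
    mosaic_ids = {s.mosaic_id for s in summaries}
    if len(mosaic_ids) != 1:
        raise FrameError(f"cannot pool summaries across mosaics: {sorted(mosaic_ids)}")
    keys = list(summaries[0].stats)
    if any(list(s.stats) != keys for s in summaries):
        raise InputError("observer summaries have mismatched class keys")

    mean: dict[str, ClassStats] = {}
    sd: dict[str, ClassStats] = {}
    of_means: dict[str, ClassStats] = {}
    n = len(summaries)
    for key in keys:
        cells = [s.stats[key] for s in summaries]
        m_kwargs, s_kwargs = {}, {}
        for f in (*_COUNT_FIELDS, *_METRIC_FIELDS):
            vals = [getattr(c, f) for c in cells]
            defined = [v for v in vals if v is not None]
            if not defined:
                m_kwargs[f], s_kwargs[f] = None, None
                continue
            m_kwargs[f] = float(np.mean(defined))
            s_kwargs[f] = float(np.std(defined, ddof=1)) if len(defined) > 1 else 0.0
        mean[key] = ClassStats(**m_kwargs)
        sd[key] = ClassStats(**s_kwargs)

        mc = mean[key]
        of_means[key] = ClassStats(
            raw_count=mc.raw_count, ref_count=mc.ref_count,
            tp=mc.tp, fp=mc.fp, fn=mc.fn,
            accuracy=_safe(accuracy, mc.tp, mc.fp, mc.fn),
            precision=_safe(precision, mc.tp, mc.fp),
            recall=_safe(recall, mc.tp, mc.fn),
            pct_diff=_safe(pct_diff, mc.raw_count, mc.ref_count),
            missing_proportion=_safe(missing_proportion, mc.fn, mc.tp),
        )
    return PooledSummary(
        mosaic_id=summaries[0].mosaic_id,
        n_observers=n,
        mean=mean,
        sd=sd,
        metrics_of_mean_counts=of_means,
    )


def correlation_report(ref_per_tile: dict[str, np.ndarray],
                       src_per_tile: dict[str, np.ndarray],
                       by_class: bool = True) -> dict[str, dict]:
    """Pearson r between reference and source per-tile counts, pooled and per class.

    Returns, per key, ``{"r": float or None, "reference": ..., "source": ...}``;
    an undefined correlation (zero variance) is flagged with ``r = None``
    rather than propagating NaN.  The paired vectors are the scatter data for
    a 1:1-line plot.
    """
    keys = [POOLED] + ([l.value for l in LABELS] if by_class else [])
    out = {}
    for key in keys:
        a = np.asarray(ref_per_tile[key], float)
        b = np.asarray(src_per_tile[key], float)
        try:
            r = per_tile_correlation(a, b)
        except UndefinedMetricError:
            r = None
        out[key] = {"r": r, "reference": a, "source": b}
    return out


def plot_correlation(report: dict[str, dict], path,
                     title: str = "per-tile counts") -> None:
    """Scatter the per-tile counts of source vs reference with the 1:1 line.

    Points on the diagonal mean the source reproduces the reference count on
    that tile exactly. Requires matplotlib (optional dependency).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = list(report)
    fig, axes = plt.subplots(1, len(keys), figsize=(4 * len(keys), 4),
                             squeeze=False)
    for ax, key in zip(axes[0], keys):
        a = report[key]["reference"]
        b = report[key]["source"]
        hi = max(1, int(max(a.max(), b.max())))
        ax.plot([0, hi], [0, hi], "k--", lw=1)
        ax.plot(a, b, "o", alpha=0.6)
        r = report[key]["r"]
        ax.set_title(f"{key} (r = {r:.2f})" if r is not None
                     else f"{key} (r undefined)")
        ax.set_xlabel("reference count")
        ax.set_ylabel("source count")
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fmt(value, decimals):
    return None if value is None else round_half_up(value, decimals)


def results_table(summaries: Sequence[SourceSummary],
                  pooled: Optional[PooledSummary] = None) -> pd.DataFrame:
    """Assemble the per-source, per-class results table (counts + rounded metrics).

    One row per source x class; proportions rounded to 2 decimals and
    percentage differences to 1, matching report formatting.  Raw values stay
    available on the summaries themselves.
    """
    rows = []
    for s in summaries:
        for key, c in s.stats.items():
            rows.append({
                "mosaic_id": s.mosaic_id, "source_id": s.source_id, "class": key,
                "raw_count": c.raw_count, "tp": c.tp, "fp": c.fp, "fn": c.fn,
                "accuracy": _fmt(c.accuracy, 2),
                "precision": _fmt(c.precision, 2),
                "recall": _fmt(c.recall, 2),
                "pct_diff": _fmt(c.pct_diff, 1),
                "missing_proportion": _fmt(c.missing_proportion, 2),
            })
    if pooled is not None:
        for key in pooled.mean:
            m, d, mm = pooled.mean[key], pooled.sd[key], pooled.metrics_of_mean_counts[key]
            rows.append({
                "mosaic_id": pooled.mosaic_id,
                "source_id": f"pooled[{pooled.n_observers}]", "class": key,
                "raw_count": m.raw_count, "tp": m.tp, "fp": m.fp, "fn": m.fn,
                "raw_count_sd": d.raw_count, "tp_sd": d.tp, "fp_sd": d.fp,
                "fn_sd": d.fn,
                "accuracy": _fmt(mm.accuracy, 2),
                "precision": _fmt(mm.precision, 2),
                "recall": _fmt(mm.recall, 2),
                "pct_diff": _fmt(mm.pct_diff, 1),
                "missing_proportion": _fmt(mm.missing_proportion, 2),
            })
    return pd.DataFrame(rows)


def misclassification_table(summary: SourceSummary) -> pd.DataFrame:
    """Counts and proportions of cross-class confusions for one source.

    One row per ordered (reference class -> predicted class) pair with a
    non-degenerate denominator; the proportion is
    n / (n + TP of the predicted-as class).
    """
    rows = []
    for ref_lab in LABELS:
        for pred_lab in LABELS:
            if ref_lab == pred_lab:
                continue
            n = summary.confusion[(ref_lab.value, pred_lab.value)]
            tp_x = summary.stats[pred_lab.value].tp
            rows.append({
                "mosaic_id": summary.mosaic_id,
                "source_id": summary.source_id,
                "confusion": f"{ref_lab.value} as {pred_lab.value}",
                "count": n,
                "proportion": (_fmt(misclass_proportion(n, tp_x), 2)
                               if (n + tp_x) > 0 else None),
            })
    return pd.DataFrame(rows)
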