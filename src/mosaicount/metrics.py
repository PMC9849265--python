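"""Summary statistics for detection-vs-reference count comparisons.

All three headline metrics are built from TP/FP/FN only — true negatives are
never used, because an object detector draws boxes on classes of interest and
"correctly detected background" is not a countable event::

    accuracy  = TP / (TP + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)

Accuracy here is the detection community's "critical success index": it is
always <= both precision and recall.  The remaining statistics mirror the
survey-comparison tables this pipeline reproduces: a signed percentage
difference of raw counts between a source and the reference observer, the
proportion of reference animals missed (= 1 - recall), the proportion of a
predicted class that is actually a misclassified other class, and per-tile
Pearson correlation between two sources' counts.

Functions return raw (unrounded) values and raise
:class:`~mosaicount.errors.UndefinedMetricError` on zero denominators rather
than reporting 0.  Reports round half-up to 2 decimals for proportions and 1
decimal for percentages via :func:`round_half_up`.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedMetricError

__all__ = [
    "accuracy",
    "precision",
    "recall",
    "pct_diff",
    "missing_proportion",
    "misclass_proportion",
    "per_tile_correlation",
    "round_half_up",
]


def _require(total: float, what: str) -> None:
    if total <= 0:
        raise UndefinedMetricError(f"{what} undefined: zero denominator")


def accuracy(tp: int, fp: int, fn: int) -> float:
    """TP / (TP + FP + FN); undefined (raises) when all counts are zero."""
    _require(tp + fp + fn, "accuracy")
    return tp / (tp + fp + fn)


def precision(tp: int, fp: int) -> float:
    """TP / (TP + FP); undefined when no positive predictions exist."""
    _require(tp + fp, "precision")
    return tp / (tp + fp)


def recall(tp: int, fn: int) -> float:
    """TP / (TP + FN); undefined when the reference has no instances."""
    _require(tp + fn, "recall")
    return tp / (tp + fn)


def pct_diff(n_test: int, n_ref: int,
             denominator: Literal["reference", "test"] = "reference") -> float:
    """Signed percentage difference between a source's count and the reference count.

    ``100 * (n_test - n_ref) / d`` where *d* is the reference count (default;
    the convention of whole-survey comparisons) or the test count (the
    convention some per-class comparisons follow).  Positive values mean the
    source over-counts relative to the reference.
    """
    d = n_ref if denominator == "reference" else n_test
    _require(d, "pct_diff")
    return 100.0 * (n_test - n_ref) / d


def missing_proportion(fn: int, tp: int) -> float:
    """FN / (TP + FN): the share of reference animals a source failed to find.

    Equals ``1 - recall`` exactly (pre-rounding).
    """
    _require(tp + fn, "missing_proportion")
    return fn / (tp + fn)


def misclass_proportion(n_y_as_x: int, tp_x: int) -> float:
    """Share of a predicted class that is really a misclassified other class.

    ``n / (n + tp_x)`` where *n* counts reference class ``y`` annotated as
    class ``x`` and ``tp_x`` the correctly-classified ``x``.  This denominator
    (misclassifications plus true positives of the *predicted-as* class) is
    the convention that reproduces the published misclassification tables.
    """
    _require(n_y_as_x + tp_x, "misclass_proportion")
    return n_y_as_x / (n_y_as_x + tp_x)


def per_tile_correlation(counts_a: Sequence[float],
                         counts_b: Sequence[float]) -> float:
    """Sample Pearson correlation between two per-tile count vectors.

    Requires equal lengths >= 3 and non-zero variance in both vectors.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count vectors must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 tiles for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedMetricError("per_tile_correlation undefined: zero variance")
    return float(stats.pearsonr(a, b).statistic)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero at the given decimal place.

    Matches hand-formatted report tables (0.125 -> 0.13), unlike banker's
    rounding. Uses the shortest decimal representation of *x*, so a float that
    *prints* as 0.865 rounds as 0.865.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
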