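"""Detection evaluation: mask IoU matching and precision/recall/F1.

Validates any upstream contour detector against ground-truth contours.
Predicted and true polygons are rasterized with the same pixel-center
semantics as the rest of the toolkit, matched greedily in order of
descending confidence at a chosen IoU threshold, and summarized as

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2PR / (P + R)

with the zero-denominator conventions P = 0 when TP+FP = 0, R = 0 when
TP+FN = 0 and F1 = 0 when P+R = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyMaskError, ParameterError
from .geometry import Polygon, _EPS, _fill_window
from .movement import FrameGeometry

__all__ = [
    "MatchResult",
    "mask_iou",
    "match_detections",
    "detection_metrics",
    "pr_sweep",
]


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    """(prediction index, truth index, IoU) for each matched pair."""


def _window_mask(poly: Polygon, x0, x1, y0, y1) -> np.ndarray:
    return _fill_window(poly.ring, x0, x1, y0, y1)


def mask_iou(a: Polygon, b: Polygon, geom: FrameGeometry) -> float:
    """Intersection-over-union of the two rasterized, frame-clipped masks.

    Raises EmptyMaskError when both masks cover no pixel (undefined IoU).
    """
    min_x = min(a.bounds()[0], b.bounds()[0])
    min_y = min(a.bounds()[1], b.bounds()[1])
    max_x = max(a.bounds()[2], b.bounds()[2])
    max_y = max(a.bounds()[3], b.bounds()[3])
    x0 = max(0, math.ceil(min_x - _EPS))
    x1 = min(geom.width - 1, math.floor(max_x + _EPS))
    y0 = max(0, math.ceil(min_y - _EPS))
    y1 = min(geom.height - 1, math.floor(max_y + _EPS))
    if x0 > x1 or y0 > y1:
        raise EmptyMaskError("both masks are empty inside the frame")
    ma = _window_mask(a, x0, x1, y0, y1)
    mb = _window_mask(b, x0, x1, y0, y1)
    union = int(np.logical_or(ma, mb).sum())
    if union == 0:
        raise EmptyMaskError("both masks are empty inside the frame")
    inter = int(np.logical_and(ma, mb).sum())
    return inter / union


def match_detections(
    preds: Sequence[tuple[Polygon, Optional[float]]],
    truths: Sequence[Polygon],
    iou_threshold: float,
    geom: FrameGeometry,
) -> MatchResult:
    """Greedy confidence-ordered matching of predictions to truths.

    Predictions are visited in descending confidence (missing confidence
    counts as 1.0; ties keep input order) and each is matched to the
    unmatched truth with the highest IoU >= threshold.  Unmatched
    predictions are false positives, unmatched truths false negatives.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ParameterError("iou_threshold must be in (0, 1]")
    order = sorted(
        range(len(preds)),
        key=lambda i: (-(preds[i][1] if preds[i][1] is not None else 1.0), i),
    )
    taken = [False] * len(truths)
    pairs: list[tuple[int, int, float]] = []
    for pi in order:
        poly = preds[pi][0]
        best_iou, best_ti = 0.0, -1
        for ti, truth in enumerate(truths):
            if taken[ti]:
                continue
            try:
                iou = mask_iou(poly, truth, geom)
            except EmptyMaskError:
                continue
            if iou > best_iou:
                best_iou, best_ti = iou, ti
        if best_ti >= 0 and best_iou >= iou_threshold:
            taken[best_ti] = True
            pairs.append((pi, best_ti, best_iou))
    tp = len(pairs)
    return MatchResult(
        tp=tp, fp=len(preds) - tp, fn=len(truths) - tp, pairs=pairs
    )


def detection_metrics(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(precision, recall, F1) from raw counts with the documented
    zero-denominator conventions."""
    if tp < 0 or fp < 0 or fn < 0:
        raise ParameterError("counts must be non-negative")
    p = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    r = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f1


def pr_sweep(
    preds: Sequence[tuple[Polygon, Optional[float]]],
    truths: Sequence[Polygon],
    geom: FrameGeometry,
    iou_threshold: float = 0.5,
    thresholds: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Precision/recall/F1 across a confidence sweep (for PR curves).

    At each confidence cutoff, predictions below the cutoff are dropped
    before matching.  Defaults to the sorted unique confidences present.
    """
    if thresholds is None:
        confs = sorted(
            {p[1] for p in preds if p[1] is not None} | {0.0}
        )
        thresholds = confs
    rows = []
    for thr in thresholds:
        kept = [p for p in preds if (p[1] if p[1] is not None else 1.0) >= thr]
        m = match_detections(kept, truths, iou_threshold, geom)
        p, r, f1 = detection_metrics(m.tp, m.fp, m.fn)
        rows.append(
            {
                "confidence": thr,
                "tp": m.tp,
                "fp": m.fp,
                "fn": m.fn,
                "precision": p,
                "recall": r,
                "f1": f1,
            }
        )
    return pd.DataFrame(rows)
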