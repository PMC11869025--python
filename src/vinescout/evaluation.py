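"""Instance-level detection metrics: IoU matching, P/R/F1, AP@0.5.

Predictions are matched to ground truth greedily by descending
confidence: each prediction claims the unmatched ground-truth instance of
highest IoU at or above the threshold (standard detector evaluation).
Matched predictions are true positives, the rest false positives;
unmatched ground truth are false negatives. From the match table:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * P * R / (P + R)

Average precision is the area under the precision envelope of the
precision-recall curve swept over every distinct confidence value
(all-point interpolation, the rule modern detector toolchains use), and
with a single class equals mAP@0.5.

IoU is computed on rasterized masks under the package-wide pixel-center
convention, because the quantity evaluated is the segmentation mask, not
the bounding box; a box-IoU mode exists behind a flag.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon, box as shapely_box
from shapely.geometry.base import BaseGeometry

from ._geometry import mask_iou as _raster_iou, rasterize_polygon
from .backends import InstanceShape


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value (e.g. no predictions
    and no ground truth at all, or AP with empty ground truth)."""


@dataclasses.dataclass
class MatchTable:
    """TP/FP/FN assignment at one IoU threshold."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]]  # (pred index, gt index, iou)
    iou_threshold: float


@dataclasses.dataclass
class PRCurve:
    thresholds: np.ndarray  # descending distinct confidences
    precision: np.ndarray
    recall: np.ndarray  # nondecreasing along the sweep
    ap: float


def iou(
    a: np.ndarray | BaseGeometry,
    b: np.ndarray | BaseGeometry,
    shape: tuple[int, int] | None = None,
    *,
    empty_is_one: bool = False,
) -> float:
    """IoU of two masks or two polygons (rasterized at ``shape``).

    Polygon inputs require ``shape``; both-empty is an error unless
    ``empty_is_one`` is set.
    """
    if isinstance(a, BaseGeometry) or isinstance(b, BaseGeometry):
        if shape is None:
            raise ValueError("shape is required to rasterize polygon inputs")
        ma = a if isinstance(a, np.ndarray) else rasterize_polygon(a, *shape)
        mb = b if isinstance(b, np.ndarray) else rasterize_polygon(b, *shape)
    else:
        ma, mb = np.asarray(a), np.asarray(b)
    return _raster_iou(ma, mb, empty_is_one=empty_is_one)


def _instance_geometry(inst: InstanceShape | Polygon, use_boxes: bool) -> BaseGeometry:
    poly = inst.polygon if isinstance(inst, InstanceShape) else inst
    return shapely_box(*poly.bounds) if use_boxes else poly


def _iou_matrix(
    preds: Sequence[InstanceShape],
    gts: Sequence[InstanceShape | Polygon],
    shape: tuple[int, int],
    use_boxes: bool,
) -> np.ndarray:
    pred_masks = [
        rasterize_polygon(_instance_geometry(p, use_boxes), *shape) for p in preds
    ]
    gt_masks = [
        rasterize_polygon(_instance_geometry(g, use_boxes), *shape) for g in gts
    ]
    mat = np.zeros((len(preds), len(gts)))
    for i, pm in enumerate(pred_masks):
        for j, gm in enumerate(gt_masks):
            mat[i, j] = _raster_iou(pm, gm, empty_is_one=True) if (pm.any() or gm.any()) else 0.0
    return mat


def _pred_order(preds: Sequence[InstanceShape], iou_mat: np.ndarray) -> list[int]:
    # descending confidence; ties broken by larger best-available IoU,
    # then original index, so the sweep is deterministic
    best = iou_mat.max(axis=1) if iou_mat.size else np.zeros(len(preds))
    return sorted(
        range(len(preds)), key=lambda i: (-preds[i].confidence, -best[i], i)
    )


def match_instances(
    preds: Sequence[InstanceShape],
    gts: Sequence[InstanceShape | Polygon],
    shape: tuple[int, int],
    iou_threshold: float = 0.5,
    use_boxes: bool = False,
) -> MatchTable:
    """Greedy confidence-ordered assignment at one IoU threshold.

    Each prediction, in descending confidence order, takes the unmatched
    ground-truth instance with the largest IoU >= threshold (ties: lower
    gt index).
    """
    mat = _iou_matrix(preds, gts, shape, use_boxes)
    taken = np.zeros(len(gts), dtype=bool)
    pairs: list[tuple[int, int, float]] = []
    for i in _pred_order(preds, mat):
        candidates = [
            (mat[i, j], j) for j in range(len(gts)) if not taken[j] and mat[i, j] >= iou_threshold
        ]
        if not candidates:
            continue
        best_iou, j = max(candidates, key=lambda c: (c[0], -c[1]))
        taken[j] = True
        pairs.append((i, j, float(best_iou)))
    tp = len(pairs)
    return MatchTable(
        tp=tp,
        fp=len(preds) - tp,
        fn=len(gts) - tp,
        pairs=pairs,
        iou_threshold=iou_threshold,
    )


def precision_recall_f1(m: MatchTable) -> tuple[float, float, float]:
    """Precision, recall and F1 from a match table.

    An undefined component (no predictions, or no ground truth) is
    returned as NaN rather than silently coerced to zero; an all-zero
    table raises.
    """
    if m.tp + m.fp + m.fn == 0:
        raise UndefinedMetricError("empty match table: no predictions, no ground truth")
    precision = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else float("nan")
    recall = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else float("nan")
    if np.isnan(precision) or np.isnan(recall):
        f1 = float("nan")
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def average_precision(
    preds: Sequence[InstanceShape],
    gts: Sequence[InstanceShape | Polygon],
    shape: tuple[int, int],
    iou_threshold: float = 0.5,
    use_boxes: bool = False,
) -> PRCurve:
    """PR curve and AP@threshold with all-point interpolation.

    The confidence sweep visits every distinct confidence value in
    descending order; because greedy matching of the top-k predictions
    does not depend on lower-ranked ones, cumulative TP/FP along a single
    full ranking equals per-threshold re-matching. AP sums recall
    increments weighted by the precision envelope (max precision at any
    recall >= the current one).
    """
    if len(gts) == 0:
        raise UndefinedMetricError("AP is undefined with empty ground truth")
    n_gt = len(gts)
    if len(preds) == 0:
        return PRCurve(
            thresholds=np.array([]), precision=np.array([]),
            recall=np.array([]), ap=0.0,
        )
    mat = _iou_matrix(preds, gts, shape, use_boxes)
    order = _pred_order(preds, mat)
    taken = np.zeros(n_gt, dtype=bool)
    is_tp = np.zeros(len(order), dtype=bool)
    confs = np.array([preds[i].confidence for i in order])
    for rank, i in enumerate(order):
        candidates = [
            (mat[i, j], j) for j in range(n_gt) if not taken[j] and mat[i, j] >= iou_threshold
        ]
        if candidates:
            _, j = max(candidates, key=lambda c: (c[0], -c[1]))
            taken[j] = True
            is_tp[rank] = True
    tp_cum = np.cumsum(is_tp)
    k = np.arange(1, len(order) + 1)
    prec_all = tp_cum / k
    rec_all = tp_cum / n_gt
    # collapse to one point per distinct confidence (the last index of
    # each tie group, i.e. the state once all ties are included)
    last_of_group = np.nonzero(np.diff(np.append(confs, -np.inf)) != 0)[0]
    thresholds = confs[last_of_group]
    precision = prec_all[last_of_group]
    recall = rec_all[last_of_group]
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for p_env, r in zip(envelope, recall):
        ap += (r - prev_r) * p_env
        prev_r = r
    return PRCurve(thresholds=thresholds, precision=precision, recall=recall, ap=float(ap))
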