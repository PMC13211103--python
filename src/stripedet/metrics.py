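"""Evaluation suite: IoU, COCO-style AP breakdowns, aspect-ratio buckets
and the Edge Concentration Score (ECS).

AP follows the COCO convention: greedy highest-score-first matching with
each ground truth used at most once, 101-point interpolated area under the
precision-recall curve, mAP averaged over classes and IoU thresholds
0.50:0.05:0.95.  Size breakdowns (AP@S/M/L at area 32^2 and 96^2) and
aspect-ratio buckets use ignore semantics: ground truths outside the
selection are ignored rather than counted, detections matching only
ignored ground truths (or themselves falling outside the selection while
unmatched) do not count as false positives.

ECS measures whether an attention map concentrates on object boundaries:
the ratio of the mean attention intensity on a 3-map-pixel strip just
inside each ground-truth box edge to the mean intensity of the whole map.
Values above 1 indicate boundary-concentrated attention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .trloss import assign_level, project_box

__all__ = ["Detection", "EvalReport", "iou", "ar_bucket",
           "average_precision", "map_suite", "ecs", "bucketed_report",
           "COCO_IOU_THRESHOLDS"]

COCO_IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
_AREA_RANGES = {"small": (0.0, 32.0 ** 2),
                "medium": (32.0 ** 2, 96.0 ** 2),
                "large": (96.0 ** 2, float("inf"))}
BUCKETS = ("G1", "G2", "G3", "G4")


@dataclass(frozen=True)
class Detection:
    box: tuple          # (x1, y1, x2, y2) pixel coords, half-open
    score: float
    class_id: int


@dataclass
class EvalReport:
    map: float = float("nan")
    ap50: float = float("nan")
    ap75: float = float("nan")
    ap_small: float | None = None
    ap_medium: float | None = None
    ap_large: float | None = None
    bucket_map: dict = field(default_factory=dict)
    bucket_ecs: dict = field(default_factory=dict)


def iou(a, b) -> float:
    """Intersection over union of two half-open pixel boxes."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    if ax2 <= ax1 or ay2 <= ay1 or bx2 <= bx1 or by2 <= by1:
        warnings.warn("degenerate box in IoU; returning 0")
        return 0.0
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def ar_bucket(box) -> str:
    """Aspect-ratio bucket: G1 AR<2.5, G2 2.5<=AR<5, G3 5<=AR<8, G4 AR>=8."""
    x1, y1, x2, y2 = box
    w, h = x2 - x1, y2 - y1
    ar = max(w, h) / min(w, h)
    if ar < 2.5:
        return "G1"
    if ar < 5.0:
        return "G2"
    if ar < 8.0:
        return "G3"
    return "G4"


def _box_area(b) -> float:
    return (b[2] - b[0]) * (b[3] - b[1])


def _select(box, area_range, bucket) -> bool:
    if area_range is not None:
        lo, hi = area_range
        if not (lo <= _box_area(box) < hi):
            return False
    if bucket is not None and ar_bucket(box) != bucket:
        return False
    return True


def _match_image(dets, gt_boxes, iou_thr, area_range=None, bucket=None):
    """Greedy per-image matching; returns ([(score, tp, ignored)], n_gt)."""
    gt_keep = [_select(g, area_range, bucket) for g in gt_boxes]
    matched = [False] * len(gt_boxes)
    records = []
    for box, score in sorted(dets, key=lambda d: -d[1]):
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gt_boxes):
            if not gt_keep[j] or matched[j]:
                continue
            v = iou(box, g)
            if v >= iou_thr and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched[best_j] = True
            records.append((score, True, False))
            continue
        hits_ignored = any((not gt_keep[j]) and iou(box, g) >= iou_thr
                           for j, g in enumerate(gt_boxes))
        if hits_ignored or not _select(box, area_range, bucket):
            records.append((score, False, True))
        else:
            records.append((score, False, False))
    return records, sum(gt_keep)


def _ap_from_records(records, n_gt) -> float | None:
    if n_gt == 0:
        return None
    records = sorted(records, key=lambda r: -r[0])
    tp = fp = 0
    rec, prec = [], []
    for _, is_tp, ignored in records:
        if ignored:
            continue
        if is_tp:
            tp += 1
        else:
            fp += 1
        rec.append(tp / n_gt)
        prec.append(tp / (tp + fp))
    rec = np.array(rec)
    prec = np.array(prec)
    total = 0.0
    for r in np.linspace(0.0, 1.0, 101):
        mask = rec >= r - 1e-12
        total += prec[mask].max() if mask.any() else 0.0
    return total / 101.0


def average_precision(dets, gts, iou_thr: float) -> float | None:
    """AP for one image and one class.

    dets: list of (box, score); gts: list of boxes.  Returns None when
    there is no ground truth (excluded from class means, per COCO
    practice).
    """
    records, n_gt = _match_image(dets, gts, iou_thr)
    return _ap_from_records(records, n_gt)


def _class_ap(dets_per_image, gts_per_image, cls, iou_thr,
              area_range=None, bucket=None) -> float | None:
    records, n_gt = [], 0
    for dets, (gt_boxes, gt_labels) in zip(dets_per_image, gts_per_image):
        d = [(tuple(x.box), float(x.score)) for x in dets if x.class_id == cls]
        g = [tuple(b) for b, l in zip(gt_boxes, gt_labels) if l == cls]
        r, n = _match_image(d, g, iou_thr, area_range, bucket)
        records.extend(r)
        n_gt += n
    return _ap_from_records(records, n_gt)


def _mean_over_classes(dets_per_image, gts_per_image, num_classes, thrs,
                       area_range=None, bucket=None) -> float | None:
    vals = []
    for cls in range(num_classes):
        aps = [_class_ap(dets_per_image, gts_per_image, cls, t,
                         area_range, bucket) for t in thrs]
        aps = [a for a in aps if a is not None]
        if aps:
            vals.append(float(np.mean(aps)))
    return float(np.mean(vals)) if vals else None


def map_suite(dets_per_image, gts_per_image, num_classes: int) -> EvalReport:
    """COCO-style report.

    dets_per_image: per-image lists of Detection; gts_per_image: per-image
    (boxes, labels) pairs.  Classes absent from every ground truth are
    excluded from the class means.
    """
    rep = EvalReport()
    m = _mean_over_classes(dets_per_image, gts_per_image, num_classes,
                           COCO_IOU_THRESHOLDS)
    rep.map = float("nan") if m is None else m
    for name, thr in (("ap50", 0.5), ("ap75", 0.75)):
        v = _mean_over_classes(dets_per_image, gts_per_image, num_classes, (thr,))
        setattr(rep, name, float("nan") if v is None else v)
    for name, rng in _AREA_RANGES.items():
        setattr(rep, f"ap_{name}",
                _mean_over_classes(dets_per_image, gts_per_image, num_classes,
                                   COCO_IOU_THRESHOLDS, area_range=rng))
    return rep


def ecs(att_map, boxes, stride: int, strip_width: int = 3):
    """Edge Concentration Score per box, plus the mean over scored boxes.

    att_map: 2-D (or 1xHxW) non-negative attention intensities; boxes:
    ground-truth pixel boxes; stride: downsampling factor mapping pixel
    coords onto the map grid.  Each box is projected with the floor/ceil
    rule, and E is the set of map pixels within `strip_width` of an edge,
    inside the box.  ECS = mean(att[E]) / mean(att).
    """
    att = np.asarray(att_map, dtype=np.float64)
    att = att.reshape(att.shape[-2], att.shape[-1])
    mu_g = att.mean()
    if mu_g <= 0:
        raise ValueError("attention map mean must be positive")
    H, W = att.shape
    scores = []
    for box in boxes:
        fbox = project_box(box, stride, extent=(W, H))
        if fbox is None:
            warnings.warn(f"box {box} empty after projection; skipped")
            scores.append(None)
            continue
        x1, y1, x2, y2 = fbox
        ys, xs = np.mgrid[y1:y2, x1:x2]
        edge = ((xs - x1 < strip_width) | (x2 - 1 - xs < strip_width) |
                (ys - y1 < strip_width) | (y2 - 1 - ys < strip_width))
        mu_e = att[ys[edge], xs[edge]].mean()
        scores.append(float(mu_e / mu_g))
    valid = [s for s in scores if s is not None]
    mean = float(np.mean(valid)) if valid else float("nan")
    return scores, mean


def bucketed_report(dets_per_image, gts_per_image, num_classes: int,
                    gate_maps_per_image=None,
                    strides=(8, 16, 32, 64)) -> EvalReport:
    """Full report plus per-aspect-ratio-bucket mAP and mean ECS.

    gate_maps_per_image: per-image lists of per-level 2-D spatial-gate
    maps (needed for the ECS columns; each ground truth is scored on the
    map of its assigned level).  Empty buckets are absent from the dicts,
    not zero.
    """
    rep = map_suite(dets_per_image, gts_per_image, num_classes)
    for bucket in BUCKETS:
        v = _mean_over_classes(dets_per_image, gts_per_image, num_classes,
                               COCO_IOU_THRESHOLDS, bucket=bucket)
        if v is not None:
            rep.bucket_map[bucket] = v
    if gate_maps_per_image is not None:
        acc = {b: [] for b in BUCKETS}
        for maps, (gt_boxes, _labels) in zip(gate_maps_per_image, gts_per_image):
            for box in gt_boxes:
                lvl = assign_level(box, strides)
                per_box, _ = ecs(maps[lvl], [box], strides[lvl])
                if per_box[0] is not None:
                    acc[ar_bucket(box)].append(per_box[0])
        for bucket, vals in acc.items():
            if vals:
                rep.bucket_ecs[bucket] = float(np.mean(vals))
    return rep
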