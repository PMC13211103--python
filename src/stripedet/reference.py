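"""Independent brute-force reference implementations.

These deliberately naive routines recompute, with explicit loops and no
shared code paths, what the fast implementations compute: the attention
block's forward pass, bilinear RoI fusion, and the detection evaluation
suite.  They exist purely for validation — tests and the acceptance
script compare the package against them on small inputs.
"""

from __future__ import annotations

import numpy as np

from .metrics import COCO_IOU_THRESHOLDS, EvalReport

__all__ = ["mslsam_forward_reference", "roi_fuse_reference",
           "reference_map_suite"]


def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def _mlp_reference(module, desc):
    """Two 1x1 convs with a rectifier, applied to a (C,) descriptor."""
    w1 = module.mlp1.weight.data[:, :, 0, 0]
    b1 = module.mlp1.bias.data
    w2 = module.mlp2.weight.data[:, :, 0, 0]
    b2 = module.mlp2.bias.data
    hidden = np.maximum(w1 @ desc + b1, 0.0)
    return w2 @ hidden + b2


def mslsam_forward_reference(module, x: np.ndarray):
    """Loop-based re-computation of the attention forward pass.

    Returns (refined, spatial_gate, strip_stack) numpy arrays.
    """
    x = np.asarray(x, dtype=np.float64)
    B, C, H, W = x.shape
    ks = module.params.kernel_lengths
    refined = np.zeros_like(x)
    gates = np.zeros((B, 1, H, W))
    stacks = np.zeros((B, len(ks), H, W))
    for b in range(B):
        f_avg = np.array([x[b, c].mean() for c in range(C)])
        f_max = np.array([x[b, c].max() for c in range(C)])
        cgate = _sigmoid(_mlp_reference(module, f_avg)
                         + _mlp_reference(module, f_max))
        xp = x[b] * cgate[:, None, None]
        fs = np.stack([xp.mean(axis=0), xp.max(axis=0)])
        for ki, k in enumerate(ks):
            wh = module.strip_h[ki].weight.data  # (1, 2, 1, k)
            bh = module.strip_h[ki].bias.data if module.strip_h[ki].bias is not None else np.zeros(1)
            wv = module.strip_v[ki].weight.data  # (1, 2, k, 1)
            bv = module.strip_v[ki].bias.data if module.strip_v[ki].bias is not None else np.zeros(1)
            half = k // 2
            for y in range(H):
                for xx in range(W):
                    ah = bh[0]
                    av = bv[0]
                    for c in range(2):
                        for u in range(k):
                            sx = xx + u - half
                            if 0 <= sx < W:
                                ah += wh[0, c, 0, u] * fs[c, y, sx]
                            sy = y + u - half
                            if 0 <= sy < H:
                                av += wv[0, c, u, 0] * fs[c, sy, xx]
                    stacks[b, ki, y, xx] = max(ah, av)
        fused = stacks[b].mean(axis=0)
        gates[b, 0] = _sigmoid(fused)
        refined[b] = xp * gates[b, 0][None]
    return refined, gates, stacks


def roi_fuse_reference(f3: np.ndarray, f4: np.ndarray, rois: np.ndarray,
                       out_size: int = 7) -> np.ndarray:
    """Loop-based bilinear RoI pooling + level averaging oracle."""

    def sample(fm, bi, x1, y1, x2, y2):
        C, H, W = fm.shape[1:]
        acc = np.zeros(C)
        for i in range(out_size):
            for j in range(out_size):
                ny = y1 + (i + 0.5) / out_size * (y2 - y1)
                nx = x1 + (j + 0.5) / out_size * (x2 - x1)
                sy = min(max(ny * H - 0.5, 0.0), H - 1.0)
                sx = min(max(nx * W - 0.5, 0.0), W - 1.0)
                y0, x0 = int(np.floor(sy)), int(np.floor(sx))
                y1i, x1i = min(y0 + 1, H - 1), min(x0 + 1, W - 1)
                fy, fx = sy - y0, sx - x0
                for c in range(C):
                    v = (fm[bi, c, y0, x0] * (1 - fy) * (1 - fx)
                         + fm[bi, c, y0, x1i] * (1 - fy) * fx
                         + fm[bi, c, y1i, x0] * fy * (1 - fx)
                         + fm[bi, c, y1i, x1i] * fy * fx)
                    acc[c] += v
        return acc / (out_size * out_size)

    outs = []
    for row in np.asarray(rois, dtype=np.float64):
        bi = int(row[0])
        v3 = sample(np.asarray(f3, dtype=np.float64), bi, *row[1:])
        v4 = sample(np.asarray(f4, dtype=np.float64), bi, *row[1:])
        outs.append((v3 + v4) / 2.0)
    return np.stack(outs)


# ------------------------------------------------- reference evaluator

def _iou_ref(a, b):
    ix1, iy1 = max(a[0], b[0]), max(a[1], b[1])
    ix2, iy2 = min(a[2], b[2]), min(a[3], b[3])
    if ix2 <= ix1 or iy2 <= iy1:
        return 0.0
    inter = (ix2 - ix1) * (iy2 - iy1)
    aa = (a[2] - a[0]) * (a[3] - a[1])
    ab = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (aa + ab - inter)


def _keep(box, area_range):
    if area_range is None:
        return True
    area = (box[2] - box[0]) * (box[3] - box[1])
    return area_range[0] <= area < area_range[1]


def _ref_class_ap(dets_per_image, gts_per_image, cls, thr, area_range):
    entries = []  # (score, image, det_index, box)
    gt_lists = []
    for i, ((gboxes, glabels), dets) in enumerate(zip(gts_per_image,
                                                      dets_per_image)):
        gt_lists.append([tuple(b) for b, l in zip(gboxes, glabels) if l == cls])
        for d in dets:
            if d.class_id == cls:
                entries.append((float(d.score), i, tuple(d.box)))
    entries.sort(key=lambda e: -e[0])
    used = [set() for _ in gt_lists]
    n_gt = sum(1 for gl in gt_lists for g in gl if _keep(g, area_range))
    if n_gt == 0:
        return None
    flags = []  # (tp, ignored)
    for score, i, box in entries:
        cand = [(j, _iou_ref(box, g)) for j, g in enumerate(gt_lists[i])
                if _keep(g, area_range) and j not in used[i]]
        cand = [(j, v) for j, v in cand if v >= thr]
        if cand:
            j = max(cand, key=lambda t: t[1])[0]
            used[i].add(j)
            flags.append((True, False))
            continue
        ign = any(_iou_ref(box, g) >= thr for g in gt_lists[i]
                  if not _keep(g, area_range))
        if ign or not _keep(box, area_range):
            flags.append((False, True))
        else:
            flags.append((False, False))
    tp = fp = 0
    curve = []
    for is_tp, ignored in flags:
        if ignored:
            continue
        tp += is_tp
        fp += not is_tp
        curve.append((tp / n_gt, tp / (tp + fp)))
    ap = 0.0
    for idx in range(101):
        r = idx / 100.0
        best = 0.0
        for rec, prec in curve:
            if rec >= r - 1e-12 and prec > best:
                best = prec
        ap += best
    return ap / 101.0


def reference_map_suite(dets_per_image, gts_per_image,
                        num_classes: int) -> EvalReport:
    areas = {"small": (0.0, 1024.0), "medium": (1024.0, 9216.0),
             "large": (9216.0, float("inf"))}

    def agg(thrs, area_range=None):
        vals = []
        for cls in range(num_classes):
            aps = [_ref_class_ap(dets_per_image, gts_per_image, cls, t,
                                 area_range) for t in thrs]
            aps = [a for a in aps if a is not None]
            if aps:
                vals.append(sum(aps) / len(aps))
        return sum(vals) / len(vals) if vals else None

    rep = EvalReport()
    m = agg(COCO_IOU_THRESHOLDS)
    rep.map = float("nan") if m is None else m
    v50 = agg((0.5,))
    v75 = agg((0.75,))
    rep.ap50 = float("nan") if v50 is None else v50
    rep.ap75 = float("nan") if v75 is None else v75
    rep.ap_small = agg(COCO_IOU_THRESHOLDS, areas["small"])
    rep.ap_medium = agg(COCO_IOU_THRESHOLDS, areas["medium"])
    rep.ap_large = agg(COCO_IOU_THRESHOLDS, areas["large"])
    return rep
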