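"""Tiny anchor-free detector carrying the stripe-attention modules.

Architecture: a small strided-conv backbone feeds a lateral/top-down neck
producing a four-level feature pyramid (strides 8/16/32/64, all levels
unified to 96 channels); every level is refined by the stripe attention
block; a shared head predicts per-cell class logits and box distances.
The backbone/neck/head are deliberately simple carriers — the scientific
content lives in the attention block and the two auxiliary losses — but
they honor the pyramid contract exactly.

Training composes   L_total = L_cls + L_loc + w_ICC * L_ICC + w_TR * L_TR
with w_ICC = 0.35 and w_TR = 0.1.  L_cls is a sigmoid focal loss over all
pyramid cells, L_loc an IoU loss at positive cells (each ground truth is
assigned to the cell containing its centre on its scale-matched level).
Both auxiliary terms are training-only: inference runs the plain
detection path.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _tensor as T
from ._tensor import Tensor, no_grad
from .icc import IccConfig, IccModule
from .metrics import Detection, iou
from .mslsam import build_attention
from .nn import SGD, Adam, Conv2d, ConvBnAct, Module, cosine_lr
from .trloss import TrConfig, assign_level, tr_loss
from .voc_io import AugmentConfig, NormalizedBox, make_paired_views, read_voc

__all__ = ["ModelConfig", "Model", "TrainingDivergedError", "build_model",
           "total_loss", "train", "predict", "save_checkpoint",
           "load_checkpoint", "load_voc_dataset"]


class TrainingDivergedError(RuntimeError):
    """Raised when a loss component goes non-finite."""


@dataclass(frozen=True)
class ModelConfig:
    num_classes: int = 3
    pyramid_channels: int = 96
    strides: tuple = (8, 16, 32, 64)
    backbone: str = "tiny"
    backbone_width: int = 16
    head_width: int = 48
    spatial_kind: str = "strip"        # strip | square | uniform
    kernel_lengths: tuple = (7, 11, 21)
    reduction: int = 16
    w_icc: float = 0.35
    w_tr: float = 0.1
    icc: IccConfig = IccConfig()
    tr: TrConfig = TrConfig()
    # optimizer defaults (cosine schedule; lr deliberately config-exposed)
    optimizer: str = "sgd"
    lr: float = 1e-5
    momentum: float = 0.937
    weight_decay: float = 0.0005
    min_lr_ratio: float = 0.01
    # inference
    score_thr: float = 0.3
    nms_iou: float = 0.5

    def __post_init__(self):
        if self.backbone not in ("tiny", "shufflenet-like"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        for a, b in zip(self.strides, self.strides[1:]):
            if b != 2 * a:
                raise ValueError("strides must double level to level")
        if self.pyramid_channels % self.reduction != 0:
            raise ValueError("reduction must divide pyramid_channels")


def _config_to_dict(cfg: ModelConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["strides"] = list(cfg.strides)
    d["kernel_lengths"] = list(cfg.kernel_lengths)
    return d


def _config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    d["strides"] = tuple(d["strides"])
    d["kernel_lengths"] = tuple(d["kernel_lengths"])
    d["icc"] = IccConfig(**d["icc"])
    d["tr"] = TrConfig(**d["tr"])
    return ModelConfig(**d)


class TinyBackbone(Module):
    """Strided 3x3 conv stack emitting stride-8/16/32/64 stages."""

    def __init__(self, width: int, rng):
        w = width
        self.stem1 = ConvBnAct(3, w, 3, 2, rng=rng)
        self.stem2 = ConvBnAct(w, 2 * w, 3, 2, rng=rng)
        self.c3 = ConvBnAct(2 * w, 4 * w, 3, 2, rng=rng)
        self.c4 = ConvBnAct(4 * w, 6 * w, 3, 2, rng=rng)
        self.c5 = ConvBnAct(6 * w, 8 * w, 3, 2, rng=rng)
        self.c6 = ConvBnAct(8 * w, 8 * w, 3, 2, rng=rng)
        self.out_channels = (4 * w, 6 * w, 8 * w, 8 * w)

    def __call__(self, x):
        x = self.stem2(self.stem1(x))
        f3 = self.c3(x)
        f4 = self.c4(f3)
        f5 = self.c5(f4)
        f6 = self.c6(f5)
        return [f3, f4, f5, f6]


class Neck(Module):
    """1x1 laterals to the unified channel width plus top-down addition."""

    def __init__(self, in_channels, out_channels: int, rng):
        self.laterals = [Conv2d(c, out_channels, 1, rng=rng) for c in in_channels]

    def __call__(self, feats):
        laterals = [lat(f) for lat, f in zip(self.laterals, feats)]
        out = [None] * len(laterals)
        out[-1] = laterals[-1]
        for i in range(len(laterals) - 2, -1, -1):
            out[i] = laterals[i] + T.upsample2(out[i + 1])
        return out


class Head(Module):
    """Shared conv tower with classification and box-distance branches."""

    def __init__(self, in_channels: int, width: int, num_classes: int, rng):
        self.tower = ConvBnAct(in_channels, width, 3, rng=rng)
        self.cls = Conv2d(width, num_classes, 1, rng=rng)
        self.reg = Conv2d(width, 4, 1, rng=rng)
        # focal-loss-friendly prior: rare positives
        self.cls.bias.data[...] = -4.0

    def __call__(self, feat):
        t = self.tower(feat)
        return self.cls(t), self.reg(t)


@dataclass
class ModelOutputs:
    levels: list          # refined pyramid features per level
    gates: list           # spatial attention gates per level
    stacks: list          # strip stacks per level
    cls: list             # class logits per level (B, K, h, w)
    reg: list             # box-distance logits per level (B, 4, h, w)


class Model(Module):
    def __init__(self, cfg: ModelConfig, rng):
        self.cfg = cfg
        self.backbone = TinyBackbone(cfg.backbone_width, rng)
        self.neck = Neck(self.backbone.out_channels, cfg.pyramid_channels, rng)
        self.attention = [
            build_attention(cfg.pyramid_channels, cfg.spatial_kind,
                            cfg.kernel_lengths, cfg.reduction, rng=rng)
            for _ in cfg.strides
        ]
        self.head = Head(cfg.pyramid_channels, cfg.head_width,
                         cfg.num_classes, rng)

    def forward(self, x: Tensor) -> ModelOutputs:
        H, W = x.shape[2], x.shape[3]
        if H % 64 or W % 64:
            raise ValueError("input spatial size must be divisible by 64")
        pyramid = self.neck(self.backbone(x))
        levels, gates, stacks, cls_outs, reg_outs = [], [], [], [], []
        for feat, att in zip(pyramid, self.attention):
            out = att(feat)
            levels.append(out.refined)
            gates.append(out.spatial_gate)
            stacks.append(out.strip_stack)
            c, r = self.head(out.refined)
            cls_outs.append(c)
            reg_outs.append(r)
        return ModelOutputs(levels, gates, stacks, cls_outs, reg_outs)

    __call__ = forward


def build_model(cfg: ModelConfig, seed: int = 0) -> Model:
    """Deterministic construction: same (cfg, seed) -> same parameters."""
    return Model(cfg, np.random.default_rng(seed))


# ------------------------------------------------------------- losses

def total_loss(l_cls, l_loc, l_icc, l_tr, cfg: ModelConfig) -> Tensor:
    """L_total = L_cls + L_loc + w_ICC * L_ICC + w_TR * L_TR."""
    comps = {"L_cls": l_cls, "L_loc": l_loc, "L_ICC": l_icc, "L_TR": l_tr}
    for name, v in comps.items():
        val = v.data if isinstance(v, Tensor) else v
        if not np.all(np.isfinite(val)):
            raise TrainingDivergedError(
                f"non-finite loss component {name}: "
                + ", ".join(f"{k}={float(np.asarray(x.data if isinstance(x, Tensor) else x)):.4g}"
                            if np.all(np.isfinite(np.asarray(x.data if isinstance(x, Tensor) else x)))
                            else f"{k}=non-finite" for k, x in comps.items()))
    l_icc = T.as_tensor(l_icc)
    l_tr = T.as_tensor(l_tr)
    return T.as_tensor(l_cls) + T.as_tensor(l_loc) \
        + cfg.w_icc * l_icc + cfg.w_tr * l_tr


def _assign_targets(boxes, labels, cfg: ModelConfig, level_shapes):
    """Centre-cell assignment on the scale-matched level."""
    cls_targets = [np.zeros((cfg.num_classes,) + s) for s in level_shapes]
    positives = []
    for box, label in zip(boxes, labels):
        lvl = assign_level(box, cfg.strides)
        stride = cfg.strides[lvl]
        h, w = level_shapes[lvl]
        cx = min(max(int((box[0] + box[2]) / 2 / stride), 0), w - 1)
        cy = min(max(int((box[1] + box[3]) / 2 / stride), 0), h - 1)
        ccx, ccy = (cx + 0.5) * stride, (cy + 0.5) * stride
        ltrb = np.array([max(ccx - box[0], 1.0), max(ccy - box[1], 1.0),
                         max(box[2] - ccx, 1.0), max(box[3] - ccy, 1.0)])
        cls_targets[lvl][label, cy, cx] = 1.0
        positives.append((lvl, cy, cx, ltrb, stride))
    return cls_targets, positives


def _focal_loss(cls_outs, cls_targets, n_pos, alpha=0.25, gamma=2.0):
    eps = 1e-12
    terms = []
    for logits, target in zip(cls_outs, cls_targets):
        y = Tensor(target)
        p = T.sigmoid(T.clip(logits, -30.0, 30.0))
        pos = y * ((1.0 - p) ** gamma) * T.log(p + eps) * (-alpha)
        neg = (1.0 - y) * (p ** gamma) * T.log(1.0 - p + eps) * (-(1.0 - alpha))
        terms.append((pos + neg).sum())
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / max(n_pos, 1))


def _iou_loss(reg_outs, positives_per_image):
    terms = []
    for b, positives in enumerate(positives_per_image):
        for (lvl, cy, cx, ltrb, stride) in positives:
            raw = reg_outs[lvl][b, :, cy, cx]
            d = T.exp(T.clip(raw, -8.0, 8.0)) * (2.0 * stride)
            tg = Tensor(ltrb)
            iw = T.minimum(d[0], tg[0]) + T.minimum(d[2], tg[2])
            ih = T.minimum(d[1], tg[1]) + T.minimum(d[3], tg[3])
            inter = iw * ih
            area_p = (d[0] + d[2]) * (d[1] + d[3])
            area_g = float((ltrb[0] + ltrb[2]) * (ltrb[1] + ltrb[3]))
            union = area_p + area_g - inter
            terms.append(1.0 - inter / union)
    if not terms:
        return Tensor(0.0)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def detection_loss(outputs: ModelOutputs, gt_boxes, gt_labels,
                   cfg: ModelConfig):
    """Focal classification + IoU localization losses for a batch."""
    level_shapes = [(c.shape[2], c.shape[3]) for c in outputs.cls]
    B = outputs.cls[0].shape[0]
    cls_targets = [np.zeros((B, cfg.num_classes) + s) for s in level_shapes]
    positives_per_image = []
    n_pos = 0
    for b in range(B):
        ct, pos = _assign_targets(gt_boxes[b], gt_labels[b], cfg, level_shapes)
        for lvl in range(len(level_shapes)):
            cls_targets[lvl][b] = ct[lvl]
        positives_per_image.append(pos)
        n_pos += len(pos)
    l_cls = _focal_loss(outputs.cls, cls_targets, n_pos)
    l_loc = _iou_loss(outputs.reg, positives_per_image)
    return l_cls, l_loc


# ------------------------------------------------------------- inference

def _nms(dets, nms_iou: float):
    dets = sorted(dets, key=lambda d: -d.score)
    keep = []
    for d in dets:
        if all(iou(d.box, k.box) < nms_iou for k in keep):
            keep.append(d)
    return keep


def image_to_input(image: np.ndarray) -> Tensor:
    x = image.astype(np.float64) / 255.0 - 0.5
    return Tensor(x.transpose(2, 0, 1)[None])


def predict(model: Model, image: np.ndarray, score_thr=None, nms_iou=None):
    """Decode head outputs to Detection list (training losses play no part).

    Deterministic for fixed weights and input.
    """
    cfg = model.cfg
    score_thr = cfg.score_thr if score_thr is None else score_thr
    nms_iou = cfg.nms_iou if nms_iou is None else nms_iou
    H, W = image.shape[:2]
    with no_grad():
        out = model(image_to_input(image))
    return decode_outputs(out, cfg, (W, H), score_thr, nms_iou)


def decode_outputs(out: ModelOutputs, cfg: ModelConfig, image_size,
                   score_thr: float, nms_iou: float, batch_index: int = 0):
    W, H = image_size
    raw = []
    for lvl, stride in enumerate(cfg.strides):
        scores = 1.0 / (1.0 + np.exp(-out.cls[lvl].data[batch_index]))
        dist = np.exp(np.clip(out.reg[lvl].data[batch_index], -8, 8)) * 2 * stride
        K, h, w = scores.shape
        for cls_id in range(K):
            ys, xs = np.nonzero(scores[cls_id] >= score_thr)
            for cy, cx in zip(ys, xs):
                ccx, ccy = (cx + 0.5) * stride, (cy + 0.5) * stride
                l, t, r, b = dist[:, cy, cx]
                box = (max(ccx - l, 0.0), max(ccy - t, 0.0),
                       min(ccx + r, W), min(ccy + b, H))
                if box[2] <= box[0] or box[3] <= box[1]:
                    continue
                raw.append(Detection(box=box, score=float(scores[cls_id, cy, cx]),
                                     class_id=cls_id))
    final = []
    for cls_id in range(cfg.num_classes):
        final.extend(_nms([d for d in raw if d.class_id == cls_id], nms_iou))
    return sorted(final, key=lambda d: -d.score)


# ------------------------------------------------------------- training

def load_voc_dataset(data_dir, split: str = "train", class_names=None):
    """Read a VOC-style tree into AnnotatedScenes with pixels attached."""
    from PIL import Image

    data_dir = Path(data_dir)
    listing = data_dir / "ImageSets" / "Main" / f"{split}.txt"
    if not listing.exists():
        raise FileNotFoundError(f"missing split listing {listing}")
    scenes = []
    for stem in listing.read_text().split():
        scene = read_voc(data_dir / "Annotations" / (stem + ".xml"),
                         class_names=class_names)
        img = np.asarray(Image.open(data_dir / "JPEGImages" / (stem + ".png")))
        scene.image = img
        scenes.append(scene)
    return scenes


def _normalized_boxes(scene) -> list:
    h, w = scene.image.shape[:2]
    return [NormalizedBox(x1 / w, y1 / h, x2 / w, y2 / h, label=l, instance_id=i)
            for i, ((x1, y1, x2, y2), l) in enumerate(zip(scene.boxes,
                                                          scene.labels))]


def _denorm(boxes, w, h):
    return [(b.x1 * w, b.y1 * h, b.x2 * w, b.y2 * h) for b in boxes]


def _batch_input(images) -> Tensor:
    arr = np.stack([im.astype(np.float64) / 255.0 - 0.5 for im in images])
    return Tensor(arr.transpose(0, 3, 1, 2))


def _clip_gradients(params, max_norm: float = 10.0):
    total = math.sqrt(sum(float((p.grad ** 2).sum())
                          for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def train(data_dir, cfg: ModelConfig, seed: int = 0, epochs: int = 1,
          batch_size: int = 4, use_icc: bool = True, use_tr: bool = True,
          aug_cfg: AugmentConfig | None = None, lr: float | None = None,
          optimizer: str | None = None, class_names=None,
          log_path=None, checkpoint_path=None, max_steps: int | None = None):
    """Train on a VOC dataset directory; returns (model, icc_module, log).

    Deterministic given seed.  The log is a per-epoch list of mean loss
    components (L_cls, L_loc, L_inst, L_cls_con, L_TR, L_total).
    """
    scenes = load_voc_dataset(data_dir, "train", class_names=class_names)
    if not scenes:
        raise ValueError(f"empty dataset under {data_dir}")
    rng = np.random.default_rng(seed)
    model = build_model(cfg, seed=seed)
    icc_mod = IccModule(cfg.icc, rng=np.random.default_rng(seed + 1))
    params = model.parameters() + (icc_mod.parameters() if use_icc else [])

    lr = cfg.lr if lr is None else lr
    opt_name = (cfg.optimizer if optimizer is None else optimizer).lower()
    if opt_name == "sgd":
        opt = SGD(params, lr=lr, momentum=cfg.momentum,
                  weight_decay=cfg.weight_decay)
    elif opt_name == "adam":
        opt = Adam(params, lr=lr, weight_decay=cfg.weight_decay)
    else:
        raise ValueError(f"unknown optimizer {opt_name!r}")

    steps_per_epoch = math.ceil(len(scenes) / batch_size)
    total_steps = epochs * steps_per_epoch
    if max_steps is not None:
        total_steps = min(total_steps, max_steps)
    aug_cfg = aug_cfg or AugmentConfig()

    log = []
    step = 0
    for epoch in range(epochs):
        order = rng.permutation(len(scenes))
        sums = {k: 0.0 for k in ("L_cls", "L_loc", "L_inst", "L_cls_con",
                                 "L_TR", "L_total")}
        n_batches = 0
        for start in range(0, len(order), batch_size):
            if step >= total_steps:
                break
            batch = [scenes[i] for i in order[start:start + batch_size]]
            if use_icc:
                views = [make_paired_views(s, aug_cfg, rng) for s in batch]
                imgs1 = [v[0] for v in views]
                boxes1 = [v[1] for v in views]
                imgs2 = [v[2] for v in views]
                boxes2 = [v[3] for v in views]
            else:
                imgs1 = [s.image for s in batch]
                boxes1 = [_normalized_boxes(s) for s in batch]
                imgs2 = boxes2 = None
            h, w = imgs1[0].shape[:2]
            out1 = model(_batch_input(imgs1))
            px_boxes = [_denorm(bs, w, h) for bs in boxes1]
            labels = [[b.label for b in bs] for bs in boxes1]
            l_cls, l_loc = detection_loss(out1, px_boxes, labels, cfg)
            l_tr = tr_loss(out1.stacks, px_boxes, cfg.tr, rng,
                           strides=cfg.strides) if use_tr else Tensor(0.0)
            l_inst = l_cls_con = Tensor(0.0)
            l_icc = Tensor(0.0)
            if use_icc:
                out2 = model(_batch_input(imgs2))
                flat1, idx1 = _flatten_views(boxes1)
                flat2, idx2 = _flatten_views(boxes2)
                if flat1:
                    l_icc, l_inst, l_cls_con = icc_mod.loss(
                        (out1.levels[1], out1.levels[2]),
                        (out2.levels[1], out2.levels[2]),
                        flat1, flat2, idx1, idx2)
            loss = total_loss(l_cls, l_loc, l_icc, l_tr, cfg)
            opt.zero_grad()
            loss.backward()
            _clip_gradients(params)
            opt.lr = cosine_lr(lr, step, total_steps, cfg.min_lr_ratio)
            opt.step()
            step += 1
            n_batches += 1
            for key, val in (("L_cls", l_cls), ("L_loc", l_loc),
                             ("L_inst", l_inst), ("L_cls_con", l_cls_con),
                             ("L_TR", l_tr), ("L_total", loss)):
                sums[key] += float(val.data)
        if n_batches:
            entry = {"epoch": epoch}
            entry.update({k: v / n_batches for k, v in sums.items()})
            log.append(entry)
        if step >= total_steps:
            break

    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(log[0]))
            writer.writeheader()
            writer.writerows(log)
    if checkpoint_path is not None:
        save_checkpoint(model, cfg, checkpoint_path, icc_module=icc_mod)
    return model, icc_mod, log


def _flatten_views(boxes_per_image):
    """Flatten per-image NormalizedBox lists, making instance ids unique
    across the batch (two views of one object still share an id)."""
    flat, idx = [], []
    for i, boxes in enumerate(boxes_per_image):
        for b in boxes:
            flat.append(dataclasses.replace(b, instance_id=b.instance_id + 10000 * i))
            idx.append(i)
    return flat, idx


# ------------------------------------------------------------- checkpoints

def save_checkpoint(model: Model, cfg: ModelConfig, path, icc_module=None):
    state = {f"model.{k}": v for k, v in model.state_dict().items()}
    if icc_module is not None:
        state.update({f"icc.{k}": v for k, v in icc_module.state_dict().items()})
    state["__config__"] = np.frombuffer(
        json.dumps(_config_to_dict(cfg)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path):
    data = np.load(path)
    cfg = _config_from_dict(json.loads(bytes(data["__config__"]).decode()))
    model = build_model(cfg, seed=0)
    model.load_state_dict({k[len("model."):]: v for k, v in data.items()
                           if k.startswith("model.")})
    icc_mod = None
    icc_state = {k[len("icc."):]: v for k, v in data.items()
                 if k.startswith("icc.")}
    if icc_state:
        icc_mod = IccModule(cfg.icc)
        icc_mod.load_state_dict(icc_state)
    return model, cfg, icc_mod
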