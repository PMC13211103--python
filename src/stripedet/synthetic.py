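"""Seeded synthetic field scenes with elongated, occluded capsule targets.

Each scene mimics the geometry that makes field fruit detection hard:
slender, optionally curved targets (capsules: rectangles with semicircular
caps, bent along a circular arc), partially covered by leaf-like occluder
blobs on a cluttered green background.  Annotation boxes are the tight
bounding boxes of the *pre-occlusion* object masks — the detector is asked
to localize the whole instance even when part of it is hidden — and a
per-object visibility fraction records how much of the mask stays exposed.

Capsules are rendered with horizontal or vertical midlines so the
annotated-box aspect ratio tracks the sampled capsule aspect ratio, which
keeps aspect-ratio bucket membership controllable from the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "SceneSpec",
    "AnnotatedScene",
    "ScenePlacementError",
    "generate_scene",
    "generate_dataset",
]


class ScenePlacementError(RuntimeError):
    """Raised when objects cannot be placed within the retry budget."""


# class palette: two green classes and a red one, so color jitter in the
# paired augmentations has something to act on
_PALETTE = np.array([[60, 110, 50], [150, 180, 60], [185, 45, 35]], dtype=float)
_BACKGROUND = np.array([46, 72, 38], dtype=float)
_LEAF = np.array([52, 125, 45], dtype=float)


@dataclass(frozen=True)
class SceneSpec:
    """Generation parameters for one synthetic scene family."""

    image_size: int = 640
    n_objects: tuple = (3, 6)          # inclusive integer range
    n_classes: int = 3
    ar_range: tuple = (4.0, 10.0)      # long side / short side, >= 1
    curvature_range: tuple = (0.0, 20.0)  # bend angle of the midline, degrees
    occlusion_fraction_range: tuple = (0.0, 0.4)
    clutter_level: float = 0.5
    seed: int = 0
    length_frac_range: tuple = (0.2, 0.45)  # long side as fraction of image

    def __post_init__(self):
        if self.ar_range[0] < 1.0 or self.ar_range[0] > self.ar_range[1]:
            raise ValueError("ar_range must satisfy 1 <= lo <= hi")
        lo, hi = self.occlusion_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("occlusion_fraction_range must lie within [0,1]")
        if not 0.0 <= self.clutter_level <= 1.0:
            raise ValueError("clutter_level must lie within [0,1]")
        if self.n_objects[0] < 0 or self.n_objects[0] > self.n_objects[1]:
            raise ValueError("n_objects must be a non-negative integer range")


@dataclass
class AnnotatedScene:
    """Image plus labeled boxes (0-based, half-open pixel coordinates)."""

    image: np.ndarray                   # H x W x 3 uint8
    boxes: list = field(default_factory=list)   # (x1, y1, x2, y2)
    labels: list = field(default_factory=list)
    visibility: list = field(default_factory=list)

    def __post_init__(self):
        h, w = self.image.shape[:2]
        if not (len(self.boxes) == len(self.labels) == len(self.visibility)):
            raise ValueError("boxes, labels, visibility must be equal-length")
        for (x1, y1, x2, y2) in self.boxes:
            if not (0 <= x1 < x2 <= w and 0 <= y1 < y2 <= h):
                raise ValueError(f"box ({x1},{y1},{x2},{y2}) outside {w}x{h} image")


def _capsule_mask(size: int, cx: float, cy: float, length: float, width: float,
                  bend_deg: float, vertical: bool):
    """Rasterize a (possibly bent) capsule; returns (mask, window offsets)."""
    radius = width / 2.0
    seg = max(length - width, 1.0)
    n_pts = max(int(seg * 2), 2)
    t = np.linspace(-0.5, 0.5, n_pts)
    if bend_deg < 1e-3:
        px = t * seg
        py = np.zeros_like(px)
    else:
        theta = np.deg2rad(bend_deg)
        R = seg / theta
        ang = t * theta
        px = R * np.sin(ang)
        py = R * (1.0 - np.cos(ang))  # sagitta bulge, recentred below
        py -= py.mean()
    if vertical:
        px, py = py, px
    xs = px + cx
    ys = py + cy

    pad = int(np.ceil(radius)) + 2
    x_lo = max(int(np.floor(xs.min())) - pad, 0)
    x_hi = min(int(np.ceil(xs.max())) + pad + 1, size)
    y_lo = max(int(np.floor(ys.min())) - pad, 0)
    y_hi = min(int(np.ceil(ys.max())) + pad + 1, size)
    win = np.ones((y_hi - y_lo, x_hi - x_lo), dtype=bool)
    ix = np.clip(np.round(xs).astype(int) - x_lo, 0, win.shape[1] - 1)
    iy = np.clip(np.round(ys).astype(int) - y_lo, 0, win.shape[0] - 1)
    win[iy, ix] = False
    dist = ndimage.distance_transform_edt(win)
    mask = dist <= radius
    return mask, dist, radius, (x_lo, y_lo)


def _ellipse_mask(shape, cy, cx, a, b, angle):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    size = spec.image_size
    img = np.tile(_BACKGROUND, (size, size, 1))
    noise = rng.normal(0.0, 1.0, (size, size, 3))
    noise = ndimage.gaussian_filter(noise, sigma=(size / 48.0, size / 48.0, 0))
    img += noise * (55.0 * spec.clutter_level + 4.0)
    # leaf-blob count scales with image area so clutter density is
    # resolution-independent
    n_blobs = int(round(3.0 * spec.clutter_level * (size / 64.0) ** 2))
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, size, 2)
        a = rng.uniform(0.02, 0.08) * size
        b = a * rng.uniform(0.4, 1.0)
        ang = rng.uniform(0, np.pi)
        m = _ellipse_mask((size, size), cy, cx, a, b, ang)
        color = _LEAF + rng.normal(0, 18, 3)
        img[m] = 0.55 * img[m] + 0.45 * color
    return img


def _box_iou(a, b) -> float:
    ix = max(0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter == 0:
        return 0.0
    area = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / area


def generate_scene(spec: SceneSpec, rng=None) -> AnnotatedScene:
    """Render one scene; fully determined by (spec, rng state)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    img = _background(spec, rng)

    n_obj = int(rng.integers(spec.n_objects[0], spec.n_objects[1] + 1))
    boxes, labels, masks = [], [], []
    for _ in range(n_obj):
        placed = False
        for _attempt in range(60):
            ar = rng.uniform(*spec.ar_range)
            length = rng.uniform(*spec.length_frac_range) * size
            width = max(length / ar, 3.0)
            length = width * ar
            bend = rng.uniform(*spec.curvature_range)
            vertical = bool(rng.integers(0, 2))
            margin = length / 2 + width + 3
            if 2 * margin >= size:
                continue
            cx = rng.uniform(margin, size - margin)
            cy = rng.uniform(margin, size - margin)
            mask, dist, radius, (x_lo, y_lo) = _capsule_mask(
                size, cx, cy, length, width, bend, vertical)
            ys, xs = np.nonzero(mask)
            if len(xs) == 0:
                continue
            box = (x_lo + int(xs.min()), y_lo + int(ys.min()),
                   x_lo + int(xs.max()) + 1, y_lo + int(ys.max()) + 1)
            if any(_box_iou(box, b) > 0.25 for b in boxes):
                continue
            label = int(rng.integers(0, spec.n_classes))
            color = _PALETTE[label % len(_PALETTE)] + rng.normal(0, 12, 3)
            shading = 0.72 + 0.55 * np.clip(1.0 - (dist / max(radius, 1e-9)) ** 2,
                                            0, 1)
            sub = img[y_lo:y_lo + mask.shape[0], x_lo:x_lo + mask.shape[1]]
            sub[mask] = color * shading[mask][:, None]
            boxes.append(box)
            labels.append(label)
            masks.append((mask, x_lo, y_lo))
            placed = True
            break
        if not placed:
            raise ScenePlacementError(
                f"could not place object {len(boxes)} of {n_obj}; "
                "spec too dense for the retry budget")

    # unannotated distractors: broad, low-aspect-ratio masses rendered with
    # the green object palettes, so local appearance alone cannot separate
    # target from background — elongation is the discriminative cue
    n_distractors = int(round(2.0 * spec.clutter_level * (size / 128.0) ** 2))
    for _ in range(n_distractors):
        for _attempt in range(20):
            length = rng.uniform(0.1, 0.18) * size
            width = length / rng.uniform(1.0, 1.8)
            cx = rng.uniform(length, size - length)
            cy = rng.uniform(length, size - length)
            mask, dist, radius, (x_lo, y_lo) = _capsule_mask(
                size, cx, cy, length, width, rng.uniform(0, 30),
                bool(rng.integers(0, 2)))
            ys, xs = np.nonzero(mask)
            if len(xs) == 0:
                continue
            dbox = (x_lo + int(xs.min()), y_lo + int(ys.min()),
                    x_lo + int(xs.max()) + 1, y_lo + int(ys.max()) + 1)
            if any(_box_iou(dbox, b) > 0.15 for b in boxes):
                continue
            label = int(rng.integers(0, 2))  # green palettes only
            color = _PALETTE[label] + rng.normal(0, 12, 3)
            shading = 0.72 + 0.55 * np.clip(
                1.0 - (dist / max(radius, 1e-9)) ** 2, 0, 1)
            sub = img[y_lo:y_lo + mask.shape[0], x_lo:x_lo + mask.shape[1]]
            sub[mask] = color * shading[mask][:, None]
            break

    # occluder blobs: drawn after all objects so they stay on top
    occ = np.zeros((size, size), dtype=bool)
    for (mask, x_lo, y_lo) in masks:
        target = rng.uniform(*spec.occlusion_fraction_range)
        if target <= 0:
            continue
        obj_area = mask.sum()
        ys, xs = np.nonzero(mask)
        obj_w = xs.max() - xs.min() + 1
        obj_h = ys.max() - ys.min() + 1
        short = min(obj_w, obj_h)
        for _try in range(60):
            gx = x_lo + xs
            gy = y_lo + ys
            covered = occ[gy, gx].sum() / obj_area
            if covered >= target:
                break
            k = rng.integers(0, len(xs))
            ccx, ccy = x_lo + xs[k], y_lo + ys[k]
            a = short * rng.uniform(0.8, 1.8)
            b = a * rng.uniform(0.45, 0.85)
            ang = rng.uniform(0, np.pi)
            m = _ellipse_mask((size, size), ccy, ccx, a, b, ang)
            color = _LEAF + rng.normal(0, 15, 3)
            img[m] = color * rng.uniform(0.85, 1.1)
            occ |= m

    visibility = []
    for (mask, x_lo, y_lo) in masks:
        ys, xs = np.nonzero(mask)
        covered = occ[y_lo + ys, x_lo + xs].sum() / mask.sum()
        visibility.append(float(1.0 - covered))

    image = np.clip(img, 0, 255).astype(np.uint8)
    return AnnotatedScene(image=image, boxes=boxes, labels=labels,
                          visibility=visibility)


def generate_dataset(spec: SceneSpec, n_images: int, out_dir,
                     class_names=None, train_frac: float = 0.8) -> dict:
    """Write a VOC-style dataset tree; returns instance-count summary.

    The whole tree (pixels and XML bytes) is a pure function of
    (spec, n_images).
    """
    from PIL import Image

    from . import voc_io
    from .metrics import ar_bucket

    out_dir = Path(out_dir)
    try:
        (out_dir / "JPEGImages").mkdir(parents=True, exist_ok=True)
        (out_dir / "Annotations").mkdir(parents=True, exist_ok=True)
        (out_dir / "ImageSets" / "Main").mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create dataset tree under {out_dir}: {e}") from e

    if class_names is None:
        class_names = [f"class_{i}" for i in range(spec.n_classes)]
    class_counts = {name: 0 for name in class_names}
    bucket_counts = {"G1": 0, "G2": 0, "G3": 0, "G4": 0}

    seeds = np.random.SeedSequence(spec.seed).spawn(n_images)
    stems = []
    for i in range(n_images):
        rng = np.random.default_rng(seeds[i])
        scene = generate_scene(spec, rng)
        stem = f"scene_{i:05d}"
        stems.append(stem)
        Image.fromarray(scene.image).save(out_dir / "JPEGImages" / (stem + ".png"))
        voc_io.write_voc(scene, out_dir / "Annotations" / (stem + ".xml"),
                         class_names=class_names, filename=stem + ".png")
        for box, label in zip(scene.boxes, scene.labels):
            class_counts[class_names[label]] += 1
            bucket_counts[ar_bucket(box)] += 1

    n_train = int(round(train_frac * n_images))
    (out_dir / "ImageSets" / "Main" / "train.txt").write_text(
        "".join(s + "\n" for s in stems[:n_train]))
    (out_dir / "ImageSets" / "Main" / "val.txt").write_text(
        "".join(s + "\n" for s in stems[n_train:]))

    return {
        "n_images": n_images,
        "class_counts": class_counts,
        "bucket_counts": bucket_counts,
    }
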