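"""Pascal VOC annotation I/O, box normalization and paired augmentation.

Internally every box is 0-based and half-open, (x1, y1, x2, y2) with
x2/y2 exclusive, so widths are plain differences.  VOC's 1-based closed
convention exists only at the XML boundary: reading maps
x1 = xmin - 1, x2 = xmax; writing inverts that.

`make_paired_views` produces the two independently augmented views needed
by the dual-level contrastive objective: each view draws its own flip,
color-jitter and region-masking parameters, geometric transforms are
applied consistently to the boxes, and photometric/masking transforms
never touch the annotations (a fully erased object keeps its box — the
reconstruction loss, not the labels, deals with invisibility).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from lxml import etree

from .synthetic import AnnotatedScene

__all__ = [
    "NormalizedBox",
    "AugmentConfig",
    "VocParseError",
    "UnknownClassError",
    "BoxBoundsError",
    "read_voc",
    "write_voc",
    "make_paired_views",
    "DEFAULT_CLASS_NAMES",
]

DEFAULT_CLASS_NAMES = ["class_0", "class_1", "class_2"]


class VocParseError(ValueError):
    """Malformed VOC XML."""


class UnknownClassError(KeyError):
    """Object class name missing from the class table."""


class BoxBoundsError(ValueError):
    """Annotation box lies outside the stated image size."""


@dataclass(frozen=True)
class NormalizedBox:
    """Box as fractions of image width/height, with identity for pairing."""

    x1: float
    y1: float
    x2: float
    y2: float
    label: int
    instance_id: int

    def __post_init__(self):
        if not (0.0 <= self.x1 < self.x2 <= 1.0 and 0.0 <= self.y1 < self.y2 <= 1.0):
            raise ValueError(f"invalid normalized box {self}")


@dataclass(frozen=True)
class AugmentConfig:
    flip_prob: float = 0.5
    brightness: float = 0.2
    contrast: float = 0.2
    saturation: float = 0.2
    hue: float = 0.03          # fraction of a full hue turn
    mask_count: tuple = (0, 3)
    mask_size: tuple = (0.05, 0.2)  # fraction of image side
    seed: int = 0

    def __post_init__(self):
        for name in ("brightness", "contrast", "saturation", "hue"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} amplitude must be non-negative")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must lie in [0,1]")


# ---------------------------------------------------------------------- XML

def read_voc(xml_path, class_names=None) -> AnnotatedScene:
    """Parse a VOC XML file (image pixels are not loaded; a placeholder
    image of the annotated size is attached)."""
    class_names = class_names or DEFAULT_CLASS_NAMES
    table = {name: i for i, name in enumerate(class_names)}
    try:
        tree = etree.parse(str(xml_path))
    except (etree.XMLSyntaxError, OSError) as e:
        raise VocParseError(f"cannot parse {xml_path}: {e}") from e
    root = tree.getroot()
    size = root.find("size")
    if size is None:
        raise VocParseError(f"{xml_path}: missing <size>")
    try:
        w = int(size.findtext("width"))
        h = int(size.findtext("height"))
    except (TypeError, ValueError) as e:
        raise VocParseError(f"{xml_path}: bad <size>") from e

    boxes, labels = [], []
    for obj in root.findall("object"):
        name = obj.findtext("name")
        if name not in table:
            raise UnknownClassError(f"{xml_path}: unknown class {name!r}")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise VocParseError(f"{xml_path}: object without <bndbox>")
        try:
            xmin = int(round(float(bnd.findtext("xmin"))))
            ymin = int(round(float(bnd.findtext("ymin"))))
            xmax = int(round(float(bnd.findtext("xmax"))))
            ymax = int(round(float(bnd.findtext("ymax"))))
        except (TypeError, ValueError) as e:
            raise VocParseError(f"{xml_path}: bad <bndbox>") from e
        box = (xmin - 1, ymin - 1, xmax, ymax)  # 1-based closed -> 0-based half-open
        if not (0 <= box[0] < box[2] <= w and 0 <= box[1] < box[3] <= h):
            raise BoxBoundsError(f"{xml_path}: box {box} outside {w}x{h}")
        boxes.append(box)
        labels.append(table[name])

    image = np.zeros((h, w, 3), dtype=np.uint8)
    return AnnotatedScene(image=image, boxes=boxes, labels=labels,
                          visibility=[1.0] * len(boxes))


def write_voc(scene: AnnotatedScene, xml_path, class_names=None,
              filename=None, folder="JPEGImages") -> None:
    class_names = class_names or DEFAULT_CLASS_NAMES
    for name in class_names:
        if not name.isascii():
            raise UnknownClassError(f"class name {name!r} is not ASCII")
    h, w = scene.image.shape[:2]
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = folder
    etree.SubElement(root, "filename").text = filename or Path(xml_path).stem + ".png"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(w)
    etree.SubElement(size, "height").text = str(h)
    etree.SubElement(size, "depth").text = "3"
    for (x1, y1, x2, y2), label in zip(scene.boxes, scene.labels):
        if label < 0 or label >= len(class_names):
            raise UnknownClassError(f"label {label} not in class table")
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = class_names[label]
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(x1 + 1)
        etree.SubElement(bnd, "ymin").text = str(y1 + 1)
        etree.SubElement(bnd, "xmax").text = str(x2)
        etree.SubElement(bnd, "ymax").text = str(y2)
    data = etree.tostring(root, pretty_print=True, encoding="unicode")
    try:
        Path(xml_path).write_text(data)
    except OSError as e:
        raise OSError(f"cannot write {xml_path}: {e}") from e


# ------------------------------------------------------------- augmentation

def _color_jitter(img: np.ndarray, cfg: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Brightness/contrast/saturation scaling plus a small hue rotation
    (YIQ chroma-plane rotation), all photometric only."""
    out = img.astype(np.float64)
    b = rng.uniform(1 - cfg.brightness, 1 + cfg.brightness)
    c = rng.uniform(1 - cfg.contrast, 1 + cfg.contrast)
    s = rng.uniform(1 - cfg.saturation, 1 + cfg.saturation)
    hshift = rng.uniform(-cfg.hue, cfg.hue) * 2 * np.pi
    out = out * b
    mean = out.mean()
    out = (out - mean) * c + mean
    gray = out.mean(axis=2, keepdims=True)
    out = gray + (out - gray) * s
    if abs(hshift) > 1e-12:
        # rotate the chroma plane around the luma axis
        y = out @ np.array([0.299, 0.587, 0.114])
        i = out @ np.array([0.596, -0.274, -0.322])
        q = out @ np.array([0.211, -0.523, 0.312])
        ci, cq = np.cos(hshift), np.sin(hshift)
        i2 = i * ci - q * cq
        q2 = i * cq + q * ci
        out = np.stack([
            y + 0.956 * i2 + 0.621 * q2,
            y - 0.272 * i2 - 0.647 * q2,
            y - 1.106 * i2 + 1.703 * q2,
        ], axis=2)
    return np.clip(out, 0, 255).astype(np.uint8)


def _region_mask(img: np.ndarray, cfg: AugmentConfig,
                 rng: np.random.Generator) -> np.ndarray:
    out = img.copy()
    h, w = out.shape[:2]
    n = int(rng.integers(cfg.mask_count[0], cfg.mask_count[1] + 1))
    for _ in range(n):
        mh = max(1, int(rng.uniform(*cfg.mask_size) * h))
        mw = max(1, int(rng.uniform(*cfg.mask_size) * w))
        y0 = int(rng.integers(0, max(h - mh, 0) + 1))
        x0 = int(rng.integers(0, max(w - mw, 0) + 1))
        out[y0:y0 + mh, x0:x0 + mw] = rng.integers(0, 256, 3, dtype=np.uint8)
    return out


def _one_view(scene: AnnotatedScene, cfg: AugmentConfig,
              rng: np.random.Generator):
    img = scene.image
    h, w = img.shape[:2]
    flipped = rng.uniform() < cfg.flip_prob
    if flipped:
        img = img[:, ::-1].copy()
    img = _color_jitter(img, cfg, rng)
    img = _region_mask(img, cfg, rng)
    boxes = []
    for iid, ((x1, y1, x2, y2), label) in enumerate(zip(scene.boxes, scene.labels)):
        nx1, nx2 = x1 / w, x2 / w
        if flipped:
            nx1, nx2 = 1.0 - nx2, 1.0 - nx1
        boxes.append(NormalizedBox(nx1, y1 / h, nx2, y2 / h,
                                   label=label, instance_id=iid))
    return img, boxes


def make_paired_views(scene: AnnotatedScene, cfg: AugmentConfig, rng=None):
    """Two independently augmented views with consistently mapped boxes.

    Returns (image1, boxes1, image2, boxes2); box lists are NormalizedBox
    lists sharing instance ids across the views.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    img1, boxes1 = _one_view(scene, cfg, rng)
    img2, boxes2 = _one_view(scene, cfg, rng)
    return img1, boxes1, img2, boxes2
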