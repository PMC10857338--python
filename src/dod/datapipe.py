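"""Dataset I/O, augmentation and the synthetic orchard generator.

Labels follow the plain-text detection convention: one object per line,
``class cx cy w h [depth]`` with center/size normalized to [0, 1] and an
optional dimensionless depth as the sixth column.  Images are PNG/JPEG
via Pillow; depth maps are float ``.npy`` arrays or 16-bit PNGs.

The synthetic generator emulates orchard benchmark imagery: bright
quasi-circular fruits of known bounding boxes scattered without overlap
over a textured green-brown background, with an analytic (planar or
radial) gradient depth map whose per-box statistics are known in closed
form.  Fruit brightness increases with proximity, giving the depth head
an appearance cue in addition to context.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .depthlabel import DepthMap, planar_gradient_backend, radial_gradient_backend, representative_depth

__all__ = [
    "LabelRecord",
    "Sample",
    "read_labels",
    "write_labels",
    "load_image",
    "save_image",
    "read_depth_map",
    "write_depth_map",
    "letterbox",
    "mosaic",
    "mixup",
    "color_jitter",
    "hflip",
    "synth_orchard",
    "coco_to_records",
]


@dataclass
class LabelRecord:
    class_id: int
    cx: float
    cy: float
    w: float
    h: float
    depth: float | None = None

    def __post_init__(self):
        if not (0 < self.w <= 1 and 0 < self.h <= 1):
            raise ValueError(f"box size out of range: {self.w}x{self.h}")
        if not (0 <= self.cx <= 1 and 0 <= self.cy <= 1):
            raise ValueError(f"box center out of unit square: ({self.cx}, {self.cy})")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")

    def to_pixels(self, img_w: int, img_h: int):
        """Corner box (x1, y1, x2, y2) in pixels."""
        x1 = (self.cx - self.w / 2) * img_w
        y1 = (self.cy - self.h / 2) * img_h
        return (x1, y1, x1 + self.w * img_w, y1 + self.h * img_h)

    @staticmethod
    def from_pixels(box, img_w: int, img_h: int, class_id: int, depth=None):
        x1, y1, x2, y2 = box
        return LabelRecord(class_id, (x1 + x2) / 2 / img_w, (y1 + y2) / 2 / img_h,
                           (x2 - x1) / img_w, (y2 - y1) / img_h, depth)


@dataclass
class Sample:
    image: np.ndarray                       # H x W x 3 uint8
    labels: list = field(default_factory=list)
    depth_map: np.ndarray | None = None     # H x W float, same frame
    image_id: str = ""


def read_labels(path) -> list:
    """Parse a 5/6-column label file; malformed lines raise with the line number."""
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise ValueError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
        try:
            cid = int(float(parts[0]))
            vals = [float(p) for p in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        depth = vals[4] if len(vals) == 5 else None
        records.append(LabelRecord(cid, *vals[:4], depth))
    return records


def write_labels(path, records) -> None:
    lines = []
    for r in records:
        base = f"{r.class_id} {r.cx:.6f} {r.cy:.6f} {r.w:.6f} {r.h:.6f}"
        lines.append(base + (f" {r.depth:.6f}" if r.depth is not None else ""))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_depth_map(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path).astype(np.float64)
    return np.asarray(Image.open(path), dtype=np.float64)


def write_depth_map(path, depth: np.ndarray) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, np.asarray(depth, dtype=np.float32))
    else:  # 16-bit PNG, values rounded to integers
        arr = np.clip(np.round(depth), 0, 65535).astype(np.uint16)
        Image.fromarray(arr, mode="I;16").save(path)


def _resize_rgb(image: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    return np.asarray(
        Image.fromarray(image).resize((out_w, out_h), Image.Resampling.BILINEAR)
    )


def letterbox(sample: Sample, size: int, pad_value: int = 114):
    """Aspect-preserving resize and gray-pad to a square `size` canvas.

    Returns the new Sample plus (scale, pad_x, pad_y) to undo the mapping.
    """
    h, w = sample.image.shape[:2]
    scale = size / max(h, w)
    nh, nw = round(h * scale), round(w * scale)
    resized = _resize_rgb(sample.image, nh, nw)
    canvas = np.full((size, size, 3), pad_value, dtype=np.uint8)
    px, py = (size - nw) // 2, (size - nh) // 2
    canvas[py : py + nh, px : px + nw] = resized
    labels = []
    for r in sample.labels:
        x1, y1, x2, y2 = r.to_pixels(w, h)
        box = (x1 * scale + px, y1 * scale + py, x2 * scale + px, y2 * scale + py)
        labels.append(LabelRecord.from_pixels(box, size, size, r.class_id, r.depth))
    depth = None
    if sample.depth_map is not None:
        from .depthlabel import resize_bilinear

        dm = resize_bilinear(sample.depth_map, nh, nw)
        depth = np.zeros((size, size))
        depth[py : py + nh, px : px + nw] = dm
    return Sample(canvas, labels, depth, sample.image_id), (scale, px, py)


def _clip_box(box, x0, y0, x1, y1):
    return (max(box[0], x0), max(box[1], y0), min(box[2], x1), min(box[3], y1))


def mosaic(samples, canvas_size: int, seed: int) -> Sample:
    """Merge four samples into one canvas split at a random center point.

    Each sample is aspect-preservingly scaled to cover its quadrant and
    cropped from the top-left; labels are mapped to canvas coordinates,
    clipped to their quadrant, and dropped once degenerate (zero area).
    """
    if len(samples) != 4:
        raise ValueError("mosaic requires exactly 4 samples")
    rng = np.random.default_rng(seed)
    s = canvas_size
    cx = int(rng.uniform(0.25, 0.75) * s)
    cy = int(rng.uniform(0.25, 0.75) * s)
    regions = [(0, 0, cx, cy), (cx, 0, s, cy), (0, cy, cx, s), (cx, cy, s, s)]
    canvas = np.zeros((s, s, 3), dtype=np.uint8)
    labels = []
    for sample, (x0, y0, x1, y1) in zip(samples, regions):
        rw, rh = x1 - x0, y1 - y0
        if rw <= 0 or rh <= 0:
            continue
        h, w = sample.image.shape[:2]
        scale = max(rw / w, rh / h)
        nh, nw = int(np.ceil(h * scale)), int(np.ceil(w * scale))
        resized = _resize_rgb(sample.image, nh, nw)
        canvas[y0:y1, x0:x1] = resized[:rh, :rw]
        for r in sample.labels:
            bx1, by1, bx2, by2 = r.to_pixels(w, h)
            box = (bx1 * scale + x0, by1 * scale + y0, bx2 * scale + x0, by2 * scale + y0)
            box = _clip_box(box, x0, y0, x1, y1)
            if box[2] - box[0] > 1e-9 and box[3] - box[1] > 1e-9:
                labels.append(LabelRecord.from_pixels(box, s, s, r.class_id, r.depth))
    return Sample(canvas, labels, None, "mosaic")


def mixup(a: Sample, b: Sample, lam: float, seed: int = 0) -> Sample:
    """Pixelwise blend λ·a + (1−λ)·b; the label lists are concatenated."""
    if a.image.shape != b.image.shape:
        raise ValueError("mixup requires equal image sizes")
    img = np.clip(
        lam * a.image.astype(np.float64) + (1 - lam) * b.image.astype(np.float64),
        0, 255,
    ).astype(np.uint8)
    return Sample(img, list(a.labels) + list(b.labels), None, "mixup")


def color_jitter(sample: Sample, p: float = 0.5, ranges=(0.4, 0.4, 0.4, 0.015),
                 seed: int = 0) -> Sample:
    """Random brightness/contrast/saturation/hue change; labels untouched."""
    rng = np.random.default_rng(seed)
    if rng.random() >= p:
        return sample
    br, ct, st, hu = ranges
    img = sample.image.astype(np.float64)
    img = img * (1 + rng.uniform(-br, br))                       # brightness
    mean = img.mean()
    img = (img - mean) * (1 + rng.uniform(-ct, ct)) + mean       # contrast
    gray = img.mean(axis=2, keepdims=True)
    img = gray + (img - gray) * (1 + rng.uniform(-st, st))       # saturation
    img = np.clip(img, 0, 255).astype(np.uint8)
    hsv = np.asarray(Image.fromarray(img).convert("HSV")).copy()
    shift = int(rng.uniform(-hu, hu) * 255)
    hsv[..., 0] = (hsv[..., 0].astype(int) + shift) % 256        # hue
    out = np.asarray(Image.fromarray(hsv, mode="HSV").convert("RGB"))
    return Sample(out, list(sample.labels), sample.depth_map, sample.image_id)


def hflip(sample: Sample, p: float = 0.5, seed: int = 0) -> Sample:
    """Horizontal mirror of pixels and labels (center-x -> 1 - center-x)."""
    rng = np.random.default_rng(seed)
    if rng.random() >= p:
        return sample
    img = sample.image[:, ::-1].copy()
    labels = [LabelRecord(r.class_id, 1.0 - r.cx, r.cy, r.w, r.h, r.depth)
              for r in sample.labels]
    depth = sample.depth_map[:, ::-1].copy() if sample.depth_map is not None else None
    return Sample(img, labels, depth, sample.image_id)


def synth_orchard(
    n_images: int,
    fruits_per_image=(1, 120),
    radius_range=(8.0, 22.0),
    image_size: int = 320,
    seed: int = 0,
    depth_style: str = "planar",
    log=lambda s: None,
) -> list:
    """Generate an orchard-style synthetic dataset with exact annotations.

    Fruits are shaded disks (class 0) placed without overlap; boxes are
    the exact disk extents.  The depth map is a planar (default) or
    radial gradient; each label's depth is computed with
    :func:`~dod.depthlabel.representative_depth`, so ground truth is
    internally consistent with the depth-label generator.  Infeasible
    packing yields fewer fruits and a log line.
    """
    if n_images < 0 or fruits_per_image[0] > fruits_per_image[1] or radius_range[0] > radius_range[1]:
        raise ValueError("invalid generator ranges")
    rng = np.random.default_rng(seed)
    backend = (
        planar_gradient_backend(z0=1.0, gy=0.02, gx=0.0)
        if depth_style == "planar"
        else radial_gradient_backend(z_center=1.0 + 0.02 * image_size, slope=0.02)
    )
    samples = []
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    for i in range(n_images):
        # textured green-brown background
        base = np.array([70, 95, 45], dtype=np.float64)
        tex = rng.normal(0, 18, size=(image_size, image_size, 3))
        patchy = rng.normal(0, 30, size=(image_size // 16, image_size // 16, 3))
        patchy = np.kron(patchy, np.ones((16, 16, 1)))
        img = np.clip(base + tex + patchy, 0, 255)

        n_fruit = int(rng.integers(fruits_per_image[0], fruits_per_image[1] + 1))
        placed = []  # (cx, cy, r)
        attempts = 0
        while len(placed) < n_fruit and attempts < 60 * n_fruit:
            attempts += 1
            r = rng.uniform(*radius_range)
            cx = rng.uniform(r + 1, image_size - r - 1)
            cy = rng.uniform(r + 1, image_size - r - 1)
            if all((cx - ox) ** 2 + (cy - oy) ** 2 > (r + orr + 2) ** 2
                   for ox, oy, orr in placed):
                placed.append((cx, cy, r))
        if len(placed) < n_fruit:
            log(f"image {i}: packed {len(placed)}/{n_fruit} fruits")

        depth = np.asarray(backend(np.zeros((image_size, image_size, 3))), dtype=np.float64)
        zmax = depth.max() + 1e-9
        labels = []
        for cx, cy, r in placed:
            box = (cx - r, cy - r, cx + r, cy + r)
            z = representative_depth(DepthMap(depth), box)
            # nearer fruit rendered brighter (illumination falloff cue)
            brightness = 0.55 + 0.45 * (z / zmax)
            dist2 = (xx - cx) ** 2 + (yy - cy) ** 2
            mask = dist2 <= r * r
            shade = 1.0 - 0.35 * np.sqrt(np.clip(dist2[mask], 0, None)) / r
            color = np.array([225, 60, 50], dtype=np.float64) * brightness
            img[mask] = np.clip(color[None, :] * shade[:, None]
                                + rng.normal(0, 6, size=(mask.sum(), 3)), 0, 255)
            labels.append(LabelRecord.from_pixels(box, image_size, image_size, 0, z))
        samples.append(Sample(img.astype(np.uint8), labels, depth, f"synth_{i:04d}"))
    return samples


def coco_to_records(coco_json: dict):
    """COCO-style JSON → {file_name: [LabelRecord, ...]} (import-only)."""
    images = {im["id"]: im for im in coco_json.get("images", [])}
    cats = sorted(c["id"] for c in coco_json.get("categories", []))
    cat_map = {cid: i for i, cid in enumerate(cats)}
    out = {images[i]["file_name"]: [] for i in images}
    for ann in coco_json.get("annotations", []):
        im = images[ann["image_id"]]
        x, y, w, h = ann["bbox"]
        rec = LabelRecord.from_pixels(
            (x, y, x + w, y + h), im["width"], im["height"], cat_map[ann["category_id"]]
        )
        out[im["file_name"]].append(rec)
    return out
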