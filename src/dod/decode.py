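"""Inference-time decoding: raw multi-scale grids → final detections.

Pipeline per cell: softmax-expectation of the four side distributions
(DFL decode), distance-to-box transform around the cell center scaled by
the level stride, confidence filtering on the sigmoid class scores, then
greedy class-wise non-maximum suppression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .net import RawPredictionSet

__all__ = [
    "Detection",
    "dfl_expect",
    "distances_to_box",
    "nms",
    "postprocess",
]


@dataclass
class Detection:
    box: tuple  # (x1, y1, x2, y2) in input-image pixels
    class_id: int
    confidence: float
    depth: float


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def dfl_expect(dist_logits: np.ndarray) -> np.ndarray:
    """Expected distance of a bin distribution: softmax · [0, 1, ..., reg_max−1].

    `dist_logits` has reg_max bins on its last axis; the result drops that
    axis and lies in [0, reg_max−1] (stride units).
    """
    reg_max = dist_logits.shape[-1]
    p = _softmax(np.asarray(dist_logits, dtype=np.float64))
    return p @ np.arange(reg_max, dtype=np.float64)


def distances_to_box(
    col: int | np.ndarray,
    row: int | np.ndarray,
    stride: float,
    l: float | np.ndarray,
    r: float | np.ndarray,
    t: float | np.ndarray,
    b: float | np.ndarray,
    image_size: tuple | None = None,
) -> np.ndarray:
    """(l,r,t,b) stride-unit distances from cell (row, col) → pixel corner box.

    The cell center sits at (col+0.5, row+0.5) grid units; distances are
    subtracted/added around it, and everything is scaled by the stride.
    When `image_size` = (W, H) is given the box is clipped to the image.
    """
    cx = (np.asarray(col, dtype=np.float64) + 0.5) * stride
    cy = (np.asarray(row, dtype=np.float64) + 0.5) * stride
    box = np.stack(
        [cx - np.asarray(l) * stride, cy - np.asarray(t) * stride,
         cx + np.asarray(r) * stride, cy + np.asarray(b) * stride],
        axis=-1,
    )
    if image_size is not None:
        w, h = image_size
        box[..., 0] = np.clip(box[..., 0], 0, w)
        box[..., 1] = np.clip(box[..., 1], 0, h)
        box[..., 2] = np.clip(box[..., 2], 0, w)
        box[..., 3] = np.clip(box[..., 3], 0, h)
    return box


def _iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of two (n,4)/(m,4) corner-box arrays."""
    a = np.asarray(boxes_a, dtype=np.float64)
    b = np.asarray(boxes_b, dtype=np.float64)
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    out = np.zeros_like(inter)
    np.divide(inter, union, out=out, where=union > 0)
    return out


def nms(detections: list[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy class-wise NMS.

    Boxes are sorted by descending confidence (ties broken by original
    index, lower first); a kept box suppresses same-class boxes whose IoU
    with it exceeds the threshold.
    """
    if not detections:
        return []
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].confidence, i))
    boxes = np.array([detections[i].box for i in order], dtype=np.float64)
    classes = np.array([detections[i].class_id for i in order])
    iou = _iou_matrix(boxes, boxes)
    keep: list[int] = []
    suppressed = np.zeros(len(order), dtype=bool)
    for i in range(len(order)):
        if suppressed[i]:
            continue
        keep.append(order[i])
        same = (classes == classes[i]) & (iou[i] > iou_threshold)
        same[: i + 1] = False
        suppressed |= same
    keep.sort()
    return [detections[i] for i in keep]


def postprocess(
    raw: RawPredictionSet,
    conf_threshold: float = 0.25,
    iou_threshold: float = 0.60,
    max_det: int = 300,
    image_size: tuple | None = None,
) -> list[Detection]:
    """Full decode of one image's raw predictions to a final detection list."""
    if not (0 <= conf_threshold <= 1 and 0 <= iou_threshold <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    cand: list[Detection] = []
    for lvl in range(raw.num_levels()):
        stride = raw.strides[lvl]
        cls_logits = np.asarray(raw.class_logits[lvl], dtype=np.float64)
        h, w, nc = cls_logits.shape
        with np.errstate(over="ignore"):
            scores = 1.0 / (1.0 + np.exp(-cls_logits))
        best_cls = scores.argmax(axis=-1)
        best_score = scores.max(axis=-1)
        rows, cols = np.nonzero(best_score >= conf_threshold)
        if rows.size == 0:
            continue
        if image_size is None:
            img_wh = (w * stride, h * stride)
        else:
            img_wh = image_size
        box_logits = np.asarray(raw.box_dist_logits[lvl], dtype=np.float64)
        sel = box_logits[rows, cols].reshape(-1, 4, raw.reg_max)
        d = dfl_expect(sel)  # (n, 4) in l,r,t,b order
        boxes = distances_to_box(cols, rows, stride, d[:, 0], d[:, 1],
                                 d[:, 2], d[:, 3], image_size=img_wh)
        depths = np.asarray(raw.depth[lvl], dtype=np.float64)[rows, cols]
        for i in range(rows.size):
            cand.append(
                Detection(
                    box=tuple(boxes[i]),
                    class_id=int(best_cls[rows[i], cols[i]]),
                    confidence=float(best_score[rows[i], cols[i]]),
                    depth=float(depths[i]),
                )
            )
    out = nms(cand, iou_threshold)
    out.sort(key=lambda d: -d.confidence)
    return out[:max_det]
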