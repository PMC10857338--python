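"""Task-aligned label assignment and the four-term training loss.

The total objective is a weighted, N_pos-normalized sum of

* a complete-IoU (CIoU) box loss — IoU, center-distance and aspect-ratio
  penalties — on foreground cells,
* binary cross-entropy classification over every cell and class, with
  alignment-normalized soft targets on foreground cells,
* a distribution focal loss (DFL) pushing probability mass onto the two
  integer bins bracketing each true box-side distance, and
* a mean-squared-error term on the representative depth of foreground
  cells,

plus (delegated to the optimizer) an L2 weight-decay term.  Foreground
cells are chosen by the task-aligned strategy: per ground-truth object,
the top-k cells (among those whose center lies inside the object box)
ranked by score^a · IoU^b.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor

__all__ = [
    "LossWeights",
    "Assignment",
    "make_anchors",
    "compute_training_loss",
    "iou",
    "aspect_term",
    "ciou_loss",
    "bce_cls_loss",
    "dfl_loss",
    "depth_mse_loss",
    "task_aligned_assign",
    "total_loss",
]

_EPS = 1e-7


@dataclass
class LossWeights:
    """Per-term weights of the training objective (all nonnegative)."""

    box: float = 7.5
    cls: float = 0.5
    dfl: float = 1.5
    depth: float = 1.0
    weight_decay: float = 5e-4

    def __post_init__(self):
        for v in (self.box, self.cls, self.dfl, self.depth, self.weight_decay):
            if not np.isfinite(v) or v < 0:
                raise ValueError("loss weights must be finite and nonnegative")


@dataclass
class Assignment:
    """Per-cell assignment of ground truths across all flattened grid cells."""

    fg_mask: np.ndarray          # (ncells,) bool
    gt_index: np.ndarray         # (ncells,) int, valid where fg
    target_boxes: np.ndarray     # (ncells, 4) pixel corners, valid where fg
    target_scores: np.ndarray    # (ncells, nc) soft classification targets
    target_depth: np.ndarray     # (ncells,) valid where fg
    align_metric: np.ndarray     # (ncells,) alignment score of the claimed gt
    n_pos: int = 0

    def __post_init__(self):
        self.n_pos = int(self.fg_mask.sum())


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def iou(box_a, box_b):
    """Intersection-over-union of two corner boxes; 0 for disjoint/degenerate.

    Accepts plain arrays (returns float/ndarray) or Tensors of shape (..., 4)
    (returns a differentiable Tensor).
    """
    if isinstance(box_a, Tensor) or isinstance(box_b, Tensor):
        a, b = _t(box_a), _t(box_b)
        ix1 = a[..., 0].maximum(b[..., 0])
        iy1 = a[..., 1].maximum(b[..., 1])
        ix2 = a[..., 2].minimum(b[..., 2])
        iy2 = a[..., 3].minimum(b[..., 3])
        inter = (ix2 - ix1).maximum(0.0) * (iy2 - iy1).maximum(0.0)
        area_a = (a[..., 2] - a[..., 0]) * (a[..., 3] - a[..., 1])
        area_b = (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])
        return inter / (area_a + area_b - inter + _EPS)
    a = np.asarray(box_a, dtype=np.float64)
    b = np.asarray(box_b, dtype=np.float64)
    iw = np.clip(np.minimum(a[..., 2], b[..., 2]) - np.maximum(a[..., 0], b[..., 0]), 0, None)
    ih = np.clip(np.minimum(a[..., 3], b[..., 3]) - np.maximum(a[..., 1], b[..., 1]), 0, None)
    inter = iw * ih
    union = (
        np.clip(a[..., 2] - a[..., 0], 0, None) * np.clip(a[..., 3] - a[..., 1], 0, None)
        + np.clip(b[..., 2] - b[..., 0], 0, None) * np.clip(b[..., 3] - b[..., 1], 0, None)
        - inter
    )
    out = np.divide(inter, union, out=np.zeros_like(inter), where=union > 0)
    return float(out) if out.ndim == 0 else out


def aspect_term(w, h, w_hat, h_hat):
    """Aspect-ratio consistency v = (4/π²)(arctan(w/h) − arctan(ŵ/ĥ))² ∈ [0, 1)."""
    if any(isinstance(x, Tensor) for x in (w, h, w_hat, h_hat)):
        w, h, w_hat, h_hat = _t(w), _t(h), _t(w_hat), _t(h_hat)
        d = (w / (h + _EPS)).arctan() - (w_hat / (h_hat + _EPS)).arctan()
        return (4.0 / np.pi**2) * d * d
    if np.any(np.asarray(w) <= 0) or np.any(np.asarray(h) <= 0) \
            or np.any(np.asarray(w_hat) <= 0) or np.any(np.asarray(h_hat) <= 0):
        raise ValueError("box dimensions must be positive")
    d = np.arctan(np.asarray(w, dtype=np.float64) / h) - np.arctan(
        np.asarray(w_hat, dtype=np.float64) / h_hat
    )
    return (4.0 / np.pi**2) * d * d


def ciou_loss(pred_box, gt_box) -> Tensor:
    """Complete-IoU loss 1 − q + ‖b−b̂‖²/ρ² + α·v per box pair.

    ρ is the diagonal of the minimum box enclosing both; α = v/(1−q+v)
    trades the aspect penalty against overlap (ε-guarded denominator).
    Inputs are (..., 4) corner boxes; returns a (...)-shaped Tensor.
    """
    p, g = _t(pred_box), _t(gt_box)
    q = iou(p, g)
    pcx, pcy = (p[..., 0] + p[..., 2]) * 0.5, (p[..., 1] + p[..., 3]) * 0.5
    gcx, gcy = (g[..., 0] + g[..., 2]) * 0.5, (g[..., 1] + g[..., 3]) * 0.5
    center_d2 = (pcx - gcx) ** 2.0 + (pcy - gcy) ** 2.0
    ex1 = p[..., 0].minimum(g[..., 0])
    ey1 = p[..., 1].minimum(g[..., 1])
    ex2 = p[..., 2].maximum(g[..., 2])
    ey2 = p[..., 3].maximum(g[..., 3])
    rho2 = (ex2 - ex1) ** 2.0 + (ey2 - ey1) ** 2.0
    v = aspect_term(p[..., 2] - p[..., 0], p[..., 3] - p[..., 1],
                    g[..., 2] - g[..., 0], g[..., 3] - g[..., 1])
    alpha = v / (1.0 - q + v + _EPS)
    return 1.0 - q + center_d2 / (rho2 + _EPS) + alpha * v


def bce_cls_loss(class_logits, targets) -> Tensor:
    """Binary cross-entropy summed over cells and classes (ŷ = sigmoid(logit)).

    Targets may be soft values in [0, 1]; log arguments are clamped.
    """
    logits = _t(class_logits)
    y = np.asarray(targets, dtype=np.float64)
    p = logits.sigmoid().clip(_EPS, 1.0 - _EPS)
    return -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()).sum()


def dfl_loss(dist_logits, target_dists, reduce: str = "sum") -> Tensor:
    """Distribution focal loss for box-side distances.

    `dist_logits` is (..., 4, reg_max); `target_dists` (..., 4) continuous
    distances in stride units within [0, reg_max−1] (values outside are
    clamped).  Per side the loss is cross-entropy onto the two bracketing
    integer bins weighted by proximity; sides are averaged per cell, then
    summed (``reduce="sum"``) or returned per cell (``reduce="none"``).
    """
    logits = _t(dist_logits)
    reg_max = logits.shape[-1]
    d = np.clip(np.asarray(target_dists, dtype=np.float64), 0.0, reg_max - 1 - 1e-6)
    lo = np.floor(d).astype(int)
    hi = lo + 1
    w_hi = d - lo
    w_lo = 1.0 - w_hi
    logp = logits.softmax(axis=-1).clip(_EPS, 1.0).log()
    idx = np.indices(d.shape)
    p_lo = logp[(*idx, lo)]
    p_hi = logp[(*idx, hi)]
    per_side = -(Tensor(w_lo) * p_lo + Tensor(w_hi) * p_hi)
    per_cell = per_side.mean(axis=-1)
    return per_cell.sum() if reduce == "sum" else per_cell


def depth_mse_loss(pred_depths, target_depths) -> Tensor:
    """Σ (z − ẑ)² over foreground cells (empty input → 0)."""
    z_hat = _t(pred_depths)
    z = np.asarray(target_depths, dtype=np.float64)
    if z.size == 0:
        return Tensor(0.0)
    d = z_hat - Tensor(z)
    return (d * d).sum()


def task_aligned_assign(
    pred_scores: np.ndarray,
    pred_boxes: np.ndarray,
    anchor_points: np.ndarray,
    gt_boxes: np.ndarray,
    gt_classes: np.ndarray,
    gt_depths: np.ndarray | None = None,
    topk: int = 10,
    alpha: float = 0.5,
    beta: float = 6.0,
) -> Assignment:
    """Assign ground truths to cells by the task-aligned metric score^a·IoU^b.

    Candidates per gt are cells whose center lies inside the gt box; the
    top-k by metric become foreground.  A cell claimed by several gts goes
    to the one with highest IoU (ties to the lowest gt index).  A gt that
    ends up with no cell falls back to the cell nearest its center.
    """
    ncells, nc = pred_scores.shape
    m = len(gt_boxes)
    empty = lambda: Assignment(
        np.zeros(ncells, bool), np.zeros(ncells, int), np.zeros((ncells, 4)),
        np.zeros((ncells, nc)), np.zeros(ncells), np.zeros(ncells))
    if m == 0:
        return empty()
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64)
    gt_classes = np.asarray(gt_classes, dtype=int)
    ax, ay = anchor_points[:, 0], anchor_points[:, 1]
    inside = (
        (ax[None] > gt_boxes[:, 0:1]) & (ax[None] < gt_boxes[:, 2:3])
        & (ay[None] > gt_boxes[:, 1:2]) & (ay[None] < gt_boxes[:, 3:4])
    )  # (m, ncells)
    overlaps = iou(gt_boxes[:, None, :], pred_boxes[None, :, :])  # (m, ncells)
    score_at_cls = pred_scores[:, gt_classes].T  # (m, ncells)
    metric = np.where(inside, score_at_cls**alpha * overlaps**beta, 0.0)

    cand = np.zeros_like(inside)
    for j in range(m):
        ids = np.nonzero(inside[j])[0]
        if ids.size == 0:
            continue
        k = min(topk, ids.size)
        top = ids[np.argsort(-metric[j, ids], kind="stable")[:k]]
        cand[j, top] = True

    # resolve multi-claimed cells by highest IoU, tie -> lowest gt index
    claimed = cand.sum(axis=0) > 0
    masked_iou = np.where(cand, overlaps, -1.0)
    gt_idx = masked_iou.argmax(axis=0)
    fg = claimed.copy()

    # fallback: a gt left without any cell takes the nearest *background*
    # cell, so claimed cells keep their highest-IoU owner
    for j in range(m):
        if not np.any(fg & (gt_idx == j) & cand[j]):
            free = np.nonzero(~fg)[0]
            if free.size == 0:
                continue
            cx = 0.5 * (gt_boxes[j, 0] + gt_boxes[j, 2])
            cy = 0.5 * (gt_boxes[j, 1] + gt_boxes[j, 3])
            near = free[np.argmin((ax[free] - cx) ** 2 + (ay[free] - cy) ** 2)]
            fg[near] = True
            gt_idx[near] = j
            cand[j, near] = True
            metric[j, near] = max(metric[j, near], _EPS)

    target_boxes = np.zeros((ncells, 4))
    target_scores = np.zeros((ncells, nc))
    target_depth = np.zeros(ncells)
    align = np.zeros(ncells)
    if np.any(fg):
        own = np.where(fg, gt_idx, -1)
        # alignment-normalized soft targets: metric scaled so that each gt's
        # best cell receives its best IoU
        metric_own = np.where((own[None] == np.arange(m)[:, None]), metric, 0.0)
        max_metric = metric_own.max(axis=1) + _EPS
        max_iou = np.where(metric_own > 0, overlaps, 0.0).max(axis=1)
        norm = metric_own * (max_iou / max_metric)[:, None]
        cells = np.nonzero(fg)[0]
        j = gt_idx[cells]
        target_boxes[cells] = gt_boxes[j]
        target_scores[cells, gt_classes[j]] = np.clip(norm[j, cells], 0.0, 1.0)
        if gt_depths is not None:
            target_depth[cells] = np.asarray(gt_depths, dtype=np.float64)[j]
        align[cells] = metric[j, cells]
    return Assignment(fg, gt_idx, target_boxes, target_scores, target_depth, align)


def total_loss(
    box_term: Tensor,
    cls_term: Tensor,
    dfl_term: Tensor,
    depth_term: Tensor,
    weights: LossWeights,
    n_pos: int,
    theta_sq_norm: float = 0.0,
) -> Tensor:
    """Weighted, N_pos-normalized combination of the four loss sums.

    With no foreground cells only the (unnormalized) classification term
    remains.  The weight-decay term φ‖θ‖² is reported when a parameter
    norm is supplied; during training the decay itself is applied through
    the optimizer's decoupled update.
    """
    reg = weights.weight_decay * theta_sq_norm
    if n_pos == 0:
        return weights.cls * _t(cls_term) + reg
    inv = 1.0 / n_pos
    return (
        weights.box * inv * _t(box_term)
        + weights.cls * inv * _t(cls_term)
        + weights.dfl * inv * _t(dfl_term)
        + weights.depth * inv * _t(depth_term)
        + reg
    )


# ---------------------------------------------------------------------------
# end-to-end training loss on raw network outputs
# ---------------------------------------------------------------------------

def make_anchors(cfg, input_size: int | None = None):
    """Flattened cell centers (pixels) and per-cell strides across all levels."""
    size = input_size or cfg.input_size
    centers, strides = [], []
    for s in cfg.strides:
        g = size // s
        xs = (np.arange(g) + 0.5) * s
        cx, cy = np.meshgrid(xs, xs)  # row-major: cy varies along axis 0
        centers.append(np.stack([cx.ravel(), cy.ravel()], axis=1))
        strides.append(np.full(g * g, s, dtype=np.float64))
    return np.concatenate(centers), np.concatenate(strides)


def _flatten_outputs(outputs):
    """Per-level NCHW head tensors → (N, ncells, C) Tensors across levels."""
    from .autograd import concat as tconcat

    box_l, cls_l, dep_l = [], [], []
    for b, c, d in outputs:
        n, cb, h, w = b.shape
        box_l.append(b.transpose(0, 2, 3, 1).reshape(n, h * w, cb))
        cls_l.append(c.transpose(0, 2, 3, 1).reshape(n, h * w, c.shape[1]))
        dep_l.append(d.transpose(0, 2, 3, 1).reshape(n, h * w))
    return tconcat(box_l, axis=1), tconcat(cls_l, axis=1), tconcat(dep_l, axis=1)


def compute_training_loss(
    outputs,
    gt_list,
    cfg,
    weights: LossWeights | None = None,
    topk: int = 10,
    tal_alpha: float = 0.5,
    tal_beta: float = 6.0,
    input_size: int | None = None,
):
    """Assign targets and evaluate the four-term loss on a forward batch.

    `outputs` is the model's per-level list of (box, cls, depth) tensors;
    `gt_list` holds one dict per image with keys ``boxes`` (m,4 pixel
    corners), ``classes`` (m,) and ``depths`` (m,).  Returns a dict with
    the differentiable ``total`` plus detached per-term values normalized
    the way they enter the total.
    """
    from .autograd import stack as tstack

    weights = weights or LossWeights()
    box_t, cls_t, dep_t = _flatten_outputs(outputs)
    n_img, ncells, _ = cls_t.shape
    reg_max = cfg.reg_max
    anchors, strides = make_anchors(cfg, input_size)
    bins = np.arange(reg_max, dtype=np.float64)

    # detached decode of every cell's box for the assigner
    bl = box_t.data.reshape(n_img, ncells, 4, reg_max).astype(np.float64)
    e = np.exp(bl - bl.max(axis=-1, keepdims=True))
    dists = (e / e.sum(axis=-1, keepdims=True)) @ bins  # (N, ncells, 4) l,r,t,b
    cx, cy = anchors[:, 0], anchors[:, 1]
    px1 = cx[None] - dists[..., 0] * strides[None]
    py1 = cy[None] - dists[..., 2] * strides[None]
    px2 = cx[None] + dists[..., 1] * strides[None]
    py2 = cy[None] + dists[..., 3] * strides[None]
    pred_boxes = np.stack([px1, py1, px2, py2], axis=-1)
    with np.errstate(over="ignore"):
        scores = 1.0 / (1.0 + np.exp(-cls_t.data.astype(np.float64)))

    tgt_scores = np.zeros((n_img, ncells, cls_t.shape[2]))
    fg_img, fg_cell = [], []
    tgt_boxes, tgt_depth = [], []
    for i in range(n_img):
        gts = gt_list[i]
        asn = task_aligned_assign(
            scores[i], pred_boxes[i], anchors,
            np.asarray(gts["boxes"], dtype=np.float64).reshape(-1, 4),
            np.asarray(gts.get("classes", []), dtype=int),
            np.asarray(gts["depths"], dtype=np.float64) if gts.get("depths") is not None else None,
            topk=topk, alpha=tal_alpha, beta=tal_beta,
        )
        tgt_scores[i] = asn.target_scores
        cells = np.nonzero(asn.fg_mask)[0]
        fg_img.append(np.full(cells.size, i))
        fg_cell.append(cells)
        tgt_boxes.append(asn.target_boxes[cells])
        tgt_depth.append(asn.target_depth[cells])
    fg_img = np.concatenate(fg_img).astype(int)
    fg_cell = np.concatenate(fg_cell).astype(int)
    n_pos = fg_img.size

    cls_term = bce_cls_loss(cls_t, tgt_scores)
    if n_pos == 0:
        zero = Tensor(0.0)
        total = total_loss(zero, cls_term, zero, zero, weights, 0)
        return {"total": total, "box": 0.0, "cls": total.item(), "dfl": 0.0,
                "depth": 0.0, "n_pos": 0}

    tgt_boxes = np.concatenate(tgt_boxes)
    tgt_depth = np.concatenate(tgt_depth)
    s_fg = strides[fg_cell]
    cx_fg, cy_fg = cx[fg_cell], cy[fg_cell]

    logits_fg = box_t[fg_img, fg_cell].reshape(n_pos, 4, reg_max)
    p = logits_fg.softmax(axis=-1)
    d_fg = (p * Tensor(np.broadcast_to(bins, (n_pos, 4, reg_max)).copy())).sum(axis=-1)
    sx = Tensor(s_fg)
    bx1 = Tensor(cx_fg) - d_fg[:, 0] * sx
    by1 = Tensor(cy_fg) - d_fg[:, 2] * sx
    bx2 = Tensor(cx_fg) + d_fg[:, 1] * sx
    by2 = Tensor(cy_fg) + d_fg[:, 3] * sx
    pred_fg = tstack([bx1, by1, bx2, by2], axis=-1)
    box_term = ciou_loss(pred_fg, tgt_boxes).sum()

    tgt_dists = np.stack(
        [(cx_fg - tgt_boxes[:, 0]) / s_fg, (tgt_boxes[:, 2] - cx_fg) / s_fg,
         (cy_fg - tgt_boxes[:, 1]) / s_fg, (tgt_boxes[:, 3] - cy_fg) / s_fg],
        axis=-1,
    )
    dfl_term = dfl_loss(logits_fg, tgt_dists)
    depth_term = depth_mse_loss(dep_t[fg_img, fg_cell], tgt_depth)

    total = total_loss(box_term, cls_term, dfl_term, depth_term, weights, n_pos)
    inv = 1.0 / n_pos
    return {
        "total": total,
        "box": box_term.item() * inv,
        "cls": cls_term.item() * inv,
        "dfl": dfl_term.item() * inv,
        "depth": depth_term.item() * inv,
        "n_pos": n_pos,
    }
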