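"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately written as plain loops over definitions,
sharing no code with the package's vectorized implementations.
"""

import numpy as np


def iou_oracle(a, b):
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union if union > 0 else 0.0


def ciou_oracle(p, g, eps=1e-7):
    q = iou_oracle(p, g)
    pc = ((p[0] + p[2]) / 2, (p[1] + p[3]) / 2)
    gc = ((g[0] + g[2]) / 2, (g[1] + g[3]) / 2)
    d2 = (pc[0] - gc[0]) ** 2 + (pc[1] - gc[1]) ** 2
    ex = max(p[2], g[2]) - min(p[0], g[0])
    ey = max(p[3], g[3]) - min(p[1], g[1])
    rho2 = ex**2 + ey**2
    v = (4 / np.pi**2) * (
        np.arctan((p[2] - p[0]) / (p[3] - p[1] + eps))
        - np.arctan((g[2] - g[0]) / (g[3] - g[1] + eps))
    ) ** 2
    alpha = v / (1 - q + v + eps)
    return 1 - q + d2 / (rho2 + eps) + alpha * v


def dfl_oracle(logits, targets):
    """Scalar-loop DFL: logits (4, reg_max), targets (4,)."""
    reg_max = logits.shape[-1]
    total = 0.0
    for side in range(4):
        d = min(max(targets[side], 0.0), reg_max - 1 - 1e-6)
        lo = int(np.floor(d))
        hi = lo + 1
        e = np.exp(logits[side] - logits[side].max())
        prob = e / e.sum()
        total += -((hi - d) * np.log(prob[lo]) + (d - lo) * np.log(prob[hi]))
    return total / 4.0


def nms_oracle(boxes, confs, classes, thr):
    """O(n^2) greedy suppression; returns kept original indices sorted."""
    order = sorted(range(len(boxes)), key=lambda i: (-confs[i], i))
    dead, keep = set(), []
    for i in order:
        if i in dead:
            continue
        keep.append(i)
        for j in order:
            if j != i and j not in dead and classes[j] == classes[i] \
                    and iou_oracle(boxes[i], boxes[j]) > thr:
                dead.add(j)
    return sorted(keep)


def ap_oracle(flags, confs, n_gt):
    """101-point interpolated AP, computed with explicit loops."""
    if n_gt == 0:
        return float("nan")
    order = sorted(range(len(flags)), key=lambda i: (-confs[i], i))
    tp = fp = 0
    pr = []  # (recall, precision) after each detection
    for i in order:
        if flags[i]:
            tp += 1
        else:
            fp += 1
        pr.append((tp / n_gt, tp / (tp + fp)))
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        best = 0.0
        for rec, prec in pr:
            if rec >= r and prec > best:
                best = prec
        ap += best / 101
    return ap


def assign_oracle(scores, pred_boxes, anchors, gt_boxes, gt_cls, topk, a, b):
    """Exhaustive task-aligned assignment on a small grid."""
    m, n = len(gt_boxes), len(anchors)
    ious = np.array([[iou_oracle(g, p) for p in pred_boxes] for g in gt_boxes])
    cand = np.zeros((m, n), dtype=bool)
    for j in range(m):
        metrics = []
        for c in range(n):
            inside = (gt_boxes[j][0] < anchors[c, 0] < gt_boxes[j][2]
                      and gt_boxes[j][1] < anchors[c, 1] < gt_boxes[j][3])
            metrics.append(
                (scores[c, gt_cls[j]] ** a) * (ious[j, c] ** b) if inside else -1.0
            )
        order = sorted((c for c in range(n) if metrics[c] >= 0),
                       key=lambda c: (-metrics[c], c))
        for c in order[:topk]:
            cand[j, c] = True
    fg = cand.any(axis=0)
    gt_idx = np.full(n, -1)
    for c in range(n):
        if fg[c]:
            js = [j for j in range(m) if cand[j, c]]
            gt_idx[c] = max(js, key=lambda j: (ious[j, c], -j))
    return fg, gt_idx
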