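"""Evaluation metrics, post-training int8 quantization, filter ablation.

Detection metrics follow the COCO protocol: greedy confidence-ordered
matching per image and class, 101-point interpolated average precision,
mAP50 and mAP50–95 (IoU 0.50:0.05:0.95), an F1–confidence curve whose
argmax fixes the reported precision/recall operating point, and the mean
squared error of the representative depth over matched true positives.

Quantization folds every conv + batch-norm pair and stores the folded
weights as signed 8-bit integers with a per-tensor scale; activation
ranges come from a calibration pass and are applied as quantize–
dequantize round trips.  The final per-task 1×1 convolutions and the
SiLU stay in float32.

The ablation study zeroes groups of mutually similar filters (normalized
weights, Euclidean distance, greedily grown from the closest pair) in a
named block and re-evaluates the detector, mirroring how grouped-filter
ablations probe which blocks carry the information the detector uses.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, asdict

import numpy as np

from .assign_loss import iou
from .autograd import no_grad
from .datapipe import Sample, letterbox
from .decode import Detection, postprocess
from .net import DOD, build_dod, save_checkpoint
from .nn import ConvBlock, Conv2d

__all__ = [
    "EvalReport",
    "match_detections",
    "average_precision",
    "depth_mse_eval",
    "evaluate",
    "quantize_model",
    "save_quantized_checkpoint",
    "similar_filter_group",
    "ablate_filters",
    "ablation_study",
]


@dataclass
class EvalReport:
    precision: float
    recall: float
    best_f1: float
    best_conf: float
    map50: float
    map50_95: float
    depth_mse: float | None
    n_images: int
    n_gts: int
    n_dets: int
    f1_curve: tuple = ()       # (confidences, f1 values)
    pr_curve: tuple = ()       # (recall grid, interpolated precision) at IoU 0.5

    def to_json(self) -> str:
        d = asdict(self)
        d["f1_curve"] = [list(map(float, a)) for a in self.f1_curve]
        d["pr_curve"] = [list(map(float, a)) for a in self.pr_curve]
        return json.dumps(d, indent=2)


def match_detections(det_boxes, det_confs, gt_boxes, iou_threshold: float):
    """Greedy one-to-one matching for a single image and class.

    Detections are visited in descending confidence (ties: lower index
    first); each claims the unmatched gt of highest IoU if that IoU
    reaches the threshold.  Returns (tp flags in input order, list of
    (det_index, gt_index) pairs).
    """
    det_boxes = np.asarray(det_boxes, dtype=np.float64).reshape(-1, 4)
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    n, m = len(det_boxes), len(gt_boxes)
    tp = np.zeros(n, dtype=bool)
    pairs = []
    if n == 0 or m == 0:
        return tp, pairs
    order = sorted(range(n), key=lambda i: (-det_confs[i], i))
    ious = iou(det_boxes[:, None, :], gt_boxes[None, :, :])
    taken = np.zeros(m, dtype=bool)
    for i in order:
        free = ~taken
        if not free.any():
            break
        j = int(np.where(free, ious[i], -1.0).argmax())
        if ious[i, j] >= iou_threshold and free[j]:
            tp[i] = True
            taken[j] = True
            pairs.append((i, j))
    return tp, pairs


def average_precision(tp_flags, confidences, n_gt: int) -> float:
    """101-point interpolated AP from confidence-ranked TP/FP flags."""
    if n_gt == 0:
        return float("nan")
    tp_flags = np.asarray(tp_flags, dtype=bool)
    if tp_flags.size == 0:
        return 0.0
    order = np.argsort(-np.asarray(confidences), kind="stable")
    tp = tp_flags[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope, sampled at 101 recall points
    env = np.maximum.accumulate(precision[::-1])[::-1]
    grid = np.linspace(0, 1, 101)
    idx = np.searchsorted(recall, grid, side="left")
    p_at = np.where(idx < len(env), env[np.clip(idx, 0, len(env) - 1)], 0.0)
    return float(p_at.mean())


def depth_mse_eval(matched_pairs) -> float | None:
    """Mean squared depth error over matched true-positive pairs.

    `matched_pairs` holds (gt_depth, predicted_depth) tuples; with no
    pairs the quantity is undefined and None is returned (never 0).
    """
    pairs = list(matched_pairs)
    if not pairs:
        return None
    return float(np.mean([(z - z_hat) ** 2 for z, z_hat in pairs]))


def _collect(per_class):
    """Flatten {cls: [(conf, tp)]} + gt counts into AP inputs."""
    aps = []
    for c, (entries, n_gt) in per_class.items():
        if n_gt == 0 and not entries:
            continue
        confs = [e[0] for e in entries]
        flags = [e[1] for e in entries]
        ap = average_precision(flags, confs, n_gt)
        if not np.isnan(ap):
            aps.append(ap)
    return float(np.mean(aps)) if aps else 0.0


def evaluate(
    model: DOD,
    samples: list,
    conf_threshold: float = 0.001,
    nms_iou: float = 0.60,
    max_det: int = 300,
) -> EvalReport:
    """Full detection + depth evaluation of a model on a sample list.

    Detections are decoded at a permissive confidence threshold so the
    PR/F1 curves cover the whole operating range; reported precision and
    recall are read at the best-F1 confidence (macro over classes).
    """
    size = model.cfg.input_size
    nc = model.cfg.num_classes
    iou_grid = np.arange(0.50, 0.96, 0.05)
    per_class = {t: {c: ([], 0) for c in range(nc)} for t in range(len(iou_grid))}
    depth_sq = []
    n_dets = n_gts = 0
    model.eval()
    for sample in samples:
        boxed, _ = letterbox(sample, size)
        chw = boxed.image.transpose(2, 0, 1).astype(np.float32) / 255.0
        raw = model.predict_raw(chw)
        dets = postprocess(raw, conf_threshold, nms_iou, max_det, (size, size))
        n_dets += len(dets)
        gt_boxes = np.array([r.to_pixels(size, size) for r in boxed.labels]).reshape(-1, 4)
        gt_cls = np.array([r.class_id for r in boxed.labels], dtype=int)
        gt_depth = np.array([r.depth if r.depth is not None else np.nan
                             for r in boxed.labels])
        n_gts += len(gt_boxes)
        for c in range(nc):
            d_idx = [i for i, d in enumerate(dets) if d.class_id == c]
            g_idx = np.nonzero(gt_cls == c)[0]
            dbox = [dets[i].box for i in d_idx]
            dconf = [dets[i].confidence for i in d_idx]
            for t, thr in enumerate(iou_grid):
                tp, pairs = match_detections(dbox, dconf, gt_boxes[g_idx], thr)
                entries, cnt = per_class[t][c]
                entries.extend(zip(dconf, tp.tolist()))
                per_class[t][c] = (entries, cnt + len(g_idx))
                if t == 0:
                    for di, gj in pairs:
                        z_gt = gt_depth[g_idx[gj]]
                        if np.isfinite(z_gt):
                            depth_sq.append((dets[d_idx[di]].depth - z_gt) ** 2)

    map50 = _collect(per_class[0])
    map50_95 = float(np.mean([_collect(per_class[t]) for t in range(len(iou_grid))]))

    # F1–confidence curve at IoU 0.5 (macro over classes with gts)
    conf_grid = np.linspace(0, 1, 201)
    f1s = np.zeros_like(conf_grid)
    ps = np.zeros_like(conf_grid)
    rs = np.zeros_like(conf_grid)
    n_cls = 0
    pr_curves = []
    for c in range(nc):
        entries, n_gt = per_class[0][c]
        if n_gt == 0:
            continue
        n_cls += 1
        arr = np.array(sorted(entries, key=lambda e: -e[0]), dtype=np.float64).reshape(-1, 2)
        confs, tps = arr[:, 0], arr[:, 1].astype(bool)
        cum_tp = np.cumsum(tps)
        cum_fp = np.cumsum(~tps)
        for k, thr in enumerate(conf_grid):
            n_keep = int(np.searchsorted(-confs, -thr, side="right"))
            if n_keep == 0:
                continue
            p = cum_tp[n_keep - 1] / max(n_keep, 1)
            r = cum_tp[n_keep - 1] / n_gt
            ps[k] += p
            rs[k] += r
            f1s[k] += 2 * p * r / (p + r) if p + r > 0 else 0.0
        # interpolated PR polyline on the recall grid
        rec = cum_tp / n_gt
        prec = cum_tp / (cum_tp + cum_fp)
        env = np.maximum.accumulate(prec[::-1])[::-1]
        grid = np.linspace(0, 1, 101)
        idx = np.searchsorted(rec, grid, side="left")
        pr_curves.append(np.where(idx < len(env), env[np.clip(idx, 0, len(env) - 1)], 0.0))
    if n_cls:
        f1s /= n_cls
        ps /= n_cls
        rs /= n_cls
    best_k = int(f1s.argmax())
    depth_mse = float(np.mean(depth_sq)) if depth_sq else None
    pr_curve = (np.linspace(0, 1, 101), np.mean(pr_curves, axis=0)) if pr_curves else ()
    return EvalReport(
        precision=float(ps[best_k]),
        recall=float(rs[best_k]),
        best_f1=float(f1s[best_k]),
        best_conf=float(conf_grid[best_k]),
        map50=map50,
        map50_95=map50_95,
        depth_mse=depth_mse,
        n_images=len(samples),
        n_gts=n_gts,
        n_dets=n_dets,
        f1_curve=(conf_grid, f1s),
        pr_curve=pr_curve,
    )


# ---------------------------------------------------------------------------
# post-training static int8 quantization
# ---------------------------------------------------------------------------

def _fold_and_quantize_block(blk: ConvBlock):
    """Fold BN into the conv, quantize the folded weight to int8.

    The folded per-channel shift is stored back in the BN tensors
    (γ=1, σ²=1−ε, μ=0, β=shift) so the module tree and every tensor
    shape stay exactly as in the float model while the arithmetic is the
    folded convolution.  Returns (int8 weight, scale).
    """
    bn = blk.bn
    scale_ch = bn.gamma.data / np.sqrt(bn.running_var + bn.eps)
    w_fold = blk.conv.weight.data * scale_ch[:, None, None, None]
    shift = bn.beta.data - bn.running_mean * scale_ch
    s_w = float(np.abs(w_fold).max() / 127.0) or 1.0
    qw = np.clip(np.round(w_fold / s_w), -127, 127).astype(np.int8)
    blk.conv.weight.data = (qw.astype(np.float32)) * s_w
    bn.gamma.data = np.ones_like(bn.gamma.data)
    bn.beta.data = shift.astype(np.float32)
    bn.running_mean = np.zeros_like(bn.running_mean)
    bn.running_var = np.full_like(bn.running_var, 1.0 - bn.eps)
    return qw, s_w


def quantize_model(model: DOD, calibration_samples: list):
    """Static int8 quantization of every conv+BN pair, with calibration.

    Returns (quantized model, report).  The quantized model keeps the
    architecture — tensor count, names and shapes are unchanged — with
    conv weights snapped to their int8 grid and activations passed
    through quantize–dequantize using ranges observed on the calibration
    samples.  The report holds the serialized sizes of both variants.
    """
    if not calibration_samples:
        raise ValueError("calibration set must be non-empty")
    size = model.cfg.input_size
    qm = build_dod(model.cfg)
    qm.load_state_dict({k: v.copy() for k, v in model.state_dict().items()})
    qm.eval()
    blocks = [m for _, m in qm.named_modules() if isinstance(m, ConvBlock)]
    for blk in blocks:
        blk.calib = {}
    with no_grad():
        for sample in calibration_samples:
            img = sample.image if isinstance(sample, Sample) else sample
            if isinstance(sample, Sample):
                boxed, _ = letterbox(sample, size)
                img = boxed.image
            qm.predict_raw(img.transpose(2, 0, 1).astype(np.float32) / 255.0)
    qstate = {}
    for name, mod in qm.named_modules():
        if isinstance(mod, ConvBlock):
            lo, hi = mod.calib["lo"], mod.calib["hi"]
            mod.calib = None
            qw, s_w = _fold_and_quantize_block(mod)
            a_scale = max(hi - lo, 1e-6) / 255.0
            zp = int(np.clip(np.round(-128 - lo / a_scale), -128, 127))
            mod.act_quant = (a_scale, zp)
            qstate[name] = (qw, s_w, mod.bn.beta.data.copy(), a_scale, zp)
    fp32_bytes = 4 * sum(p.data.size for p in model.parameters())
    int8_bytes = 0
    for name, mod in qm.named_modules():
        if isinstance(mod, ConvBlock):
            int8_bytes += mod.conv.weight.data.size          # 1 byte per int8 weight
            int8_bytes += 4 * mod.bn.beta.data.size + 8      # fp32 shift + scales
        elif isinstance(mod, Conv2d) and not any(
            mod is b.conv for b in blocks
        ):
            int8_bytes += 4 * mod.weight.data.size
            if mod.bias is not None:
                int8_bytes += 4 * mod.bias.data.size
    report = {
        "fp32_bytes": int(fp32_bytes),
        "int8_bytes": int(int8_bytes),
        "size_ratio": int8_bytes / fp32_bytes,
        "n_quantized_blocks": len(blocks),
        "qstate": qstate,
    }
    return qm, report


def save_quantized_checkpoint(path, qm: DOD, report: dict) -> None:
    """Archive with int8 weight tensors for quantized blocks, fp32 elsewhere."""
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        zf.writestr("config.json", qm.cfg.to_json())
        manifest = {}
        qnames = report["qstate"]
        quantized_convs = {
            id(mod.conv) for name, mod in qm.named_modules() if name in qnames
        }
        for name, mod in qm.named_modules():
            if isinstance(mod, Conv2d) and id(mod) in quantized_convs:
                continue  # stored in int8 under its ConvBlock
            if name in qnames:
                qw, s_w, shift, a_scale, zp = qnames[name]
                manifest[name] = {"shape": list(qw.shape), "dtype": "int8",
                                  "w_scale": s_w, "act_scale": a_scale, "act_zp": zp}
                zf.writestr(f"tensors/{name}.weight.int8", qw.tobytes())
                zf.writestr(f"tensors/{name}.shift", shift.astype("<f4").tobytes())
            elif isinstance(mod, Conv2d):
                manifest[name] = {"shape": list(mod.weight.data.shape), "dtype": "f4"}
                zf.writestr(f"tensors/{name}.weight", mod.weight.data.astype("<f4").tobytes())
                if mod.bias is not None:
                    zf.writestr(f"tensors/{name}.bias", mod.bias.data.astype("<f4").tobytes())
        zf.writestr("manifest.json", json.dumps(manifest))


# ---------------------------------------------------------------------------
# grouped-filter ablation
# ---------------------------------------------------------------------------

def similar_filter_group(weights: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k most mutually similar filters.

    Each filter's weight vector is normalized to unit length; pairwise
    Euclidean distances are computed; the group starts from the closest
    pair and greedily adds the filter with minimum average distance to
    the current group.
    """
    f = weights.reshape(len(weights), -1).astype(np.float64)
    if k <= 0:
        return np.array([], dtype=int)
    if k >= len(f):
        return np.arange(len(f))
    norms = np.linalg.norm(f, axis=1, keepdims=True)
    fn = f / np.where(norms > 0, norms, 1.0)
    d = np.linalg.norm(fn[:, None, :] - fn[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    group = [min(i, j), max(i, j)]
    while len(group) < k:
        rest = np.setdiff1d(np.arange(len(f)), group)
        avg = d[np.ix_(rest, group)].mean(axis=1)
        group.append(int(rest[int(avg.argmin())]))
    return np.array(sorted(group[:k]), dtype=int)


def _block_convs(block):
    """(conv, following-bn-or-None) pairs inside a block, in graph order."""
    out = []
    for _, mod in block.named_modules():
        if isinstance(mod, ConvBlock):
            out.append((mod.conv, mod.bn))
    for _, mod in block.named_modules():
        if isinstance(mod, Conv2d) and not any(mod is c for c, _ in out):
            out.append((mod, None))
    return out


def ablate_filters(model: DOD, block_name: str, proportion: float) -> DOD:
    """Zero the most similar ⌈p·F⌉ filters of every conv layer in a block.

    Returns an ablated copy.  For each selected filter the conv weights,
    conv bias and the channel's batch-norm affine/statistics are zeroed,
    so the filter's output activation is exactly zero on any input.
    """
    if not (0 <= proportion <= 1):
        raise ValueError("proportion must lie in [0, 1]")
    am = build_dod(model.cfg)
    am.load_state_dict({k: v.copy() for k, v in model.state_dict().items()})
    block = dict(am.named_modules()).get(block_name)
    if block is None:
        raise KeyError(f"no block named {block_name!r}")
    convs = _block_convs(block)
    if not isinstance(block, (ConvBlock,)) and not convs:
        raise ValueError(f"block {block_name!r} contains no convolutional filters")
    for conv, bn in convs:
        k = int(np.ceil(proportion * conv.cout))
        sel = similar_filter_group(conv.weight.data, k)
        if sel.size == 0:
            continue
        conv.weight.data[sel] = 0.0
        if conv.bias is not None:
            conv.bias.data[sel] = 0.0
        if bn is not None:
            bn.gamma.data[sel] = 0.0
            bn.beta.data[sel] = 0.0
            bn.running_mean[sel] = 0.0
    return am


def ablation_study(model: DOD, samples: list, proportions=(0.1, 0.25, 0.5),
                   blocks=None, **eval_kw) -> list:
    """Evaluate metric deltas per (block × ablation proportion).

    Returns rows of dicts with the block, proportion, mAP50, mAP50–95
    and depth MSE of the ablated model, plus the unablated baseline as
    proportion 0.
    """
    if blocks is None:
        blocks = [n for n, m in model.named_modules()
                  if n and "." not in n and _block_convs(m)]
    base = evaluate(model, samples, **eval_kw)
    rows = [{"block": "none", "proportion": 0.0, "map50": base.map50,
             "map50_95": base.map50_95, "depth_mse": base.depth_mse}]
    for b in blocks:
        for p in proportions:
            rep = evaluate(ablate_filters(model, b, p), samples, **eval_kw)
            rows.append({"block": b, "proportion": p, "map50": rep.map50,
                         "map50_95": rep.map50_95, "depth_mse": rep.depth_mse})
    return rows
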