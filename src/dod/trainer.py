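"""Training loop: schedules, AMSGrad optimizer, histories, checkpoints.

The learning rate warms up linearly from ``lr_start`` to ``lr_peak`` over
the first ``warmup_epochs`` and then follows a cosine annealing from
``lr_peak`` down to ``lr_end``; both phases are interpolated per step.
Weights are updated with the adaptive-moment optimizer in its AMSGrad
variant (max-corrected second moment) and decoupled weight decay, which
realizes the φ‖θ‖² regularization term of the objective.  Model
selection keeps the epoch with the lowest validation loss, computed with
augmentation off and running batch-norm statistics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np

from .assign_loss import LossWeights, compute_training_loss
from .autograd import Tensor, no_grad
from .datapipe import Sample, color_jitter, hflip, letterbox, mixup, mosaic
from .net import DOD, save_checkpoint
from .nn import BatchNorm2d

__all__ = ["TrainConfig", "lr_at", "AmsGrad", "train", "recalibrate_bn"]


@dataclass
class TrainConfig:
    epochs: int = 100
    warmup_epochs: int = 3
    lr_start: float = 1e-4
    lr_peak: float = 1e-3
    lr_end: float = 1e-4
    batch_size: int = 4
    seed: int = 0
    steps_per_epoch: int = 1          # set by train() from the dataset
    betas: tuple = (0.9, 0.999)
    eps: float = 1e-8
    grad_clip_norm: float = 10.0
    mosaic_until: int = 0             # epochs with mosaic on (0 = off)
    mixup_until: int = 0
    color_jitter_p: float = 0.0
    hflip_p: float = 0.0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    tal_topk: int = 10
    tal_alpha: float = 0.5
    tal_beta: float = 6.0

    def __post_init__(self):
        if self.warmup_epochs > self.epochs:
            raise ValueError("warmup_epochs must not exceed epochs")
        for r in (self.lr_start, self.lr_peak, self.lr_end):
            if r <= 0:
                raise ValueError("learning rates must be positive")


def lr_at(step: int, cfg: TrainConfig) -> float:
    """Learning rate at a global step (per-step interpolation).

    Linear from lr_start to lr_peak across the warmup steps, then cosine
    from lr_peak to lr_end across the remaining steps; continuous at the
    junction and monotone within each phase.
    """
    spe = max(cfg.steps_per_epoch, 1)
    total = cfg.epochs * spe
    warm = cfg.warmup_epochs * spe
    if step < warm:
        return cfg.lr_start + (cfg.lr_peak - cfg.lr_start) * step / max(warm, 1)
    span = max(total - warm, 1)
    t = min(step - warm, span) / span
    return cfg.lr_end + 0.5 * (cfg.lr_peak - cfg.lr_end) * (1 + np.cos(np.pi * t))


class AmsGrad:
    """Adam with the max-corrected second moment and decoupled weight decay."""

    def __init__(self, params, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.vhat = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            np.maximum(self.vhat[i], self.v[i], out=self.vhat[i])
            update = (self.m[i] / bc1) / (np.sqrt(self.vhat[i] / bc2) + self.eps)
            if self.weight_decay:
                p.data *= 1.0 - lr * self.weight_decay
            p.data -= (lr * update).astype(p.data.dtype)


def _prepare(sample: Sample, size: int):
    """Letterbox + normalize one sample to (chw float32, gt dict)."""
    boxed, _ = letterbox(sample, size)
    chw = np.ascontiguousarray(boxed.image.transpose(2, 0, 1)).astype(np.float32) / 255.0
    boxes, classes, depths = [], [], []
    for r in boxed.labels:
        boxes.append(r.to_pixels(size, size))
        classes.append(r.class_id)
        depths.append(r.depth if r.depth is not None else 0.0)
    gts = {
        "boxes": np.asarray(boxes, dtype=np.float64).reshape(-1, 4),
        "classes": np.asarray(classes, dtype=int),
        "depths": np.asarray(depths, dtype=np.float64),
    }
    return chw, gts


def _augment(samples, epoch, cfg: TrainConfig, rng: np.random.Generator, size: int):
    pool = list(samples)
    out = []
    for s in pool:
        if epoch < cfg.mosaic_until and len(pool) >= 4:
            picks = [pool[j] for j in rng.integers(0, len(pool), 4)]
            s = mosaic(picks, size, int(rng.integers(0, 2**31 - 1)))
        if epoch < cfg.mixup_until:
            other = pool[int(rng.integers(0, len(pool)))]
            if other.image.shape == s.image.shape:
                lam = float(rng.beta(32.0, 32.0))
                s = mixup(s, other, lam)
        if cfg.color_jitter_p > 0:
            s = color_jitter(s, p=cfg.color_jitter_p, seed=int(rng.integers(0, 2**31 - 1)))
        if cfg.hflip_p > 0:
            s = hflip(s, p=cfg.hflip_p, seed=int(rng.integers(0, 2**31 - 1)))
        out.append(s)
    return out


def recalibrate_bn(model: DOD, prepared, batch_size: int = 8) -> None:
    """Recompute batch-norm running statistics as exact dataset averages.

    The slow running-stat momentum (0.03) is tuned for long schedules; on
    short runs the stored statistics lag the trained activations badly,
    so inference-mode outputs diverge from training-mode ones.  A single
    unaugmented pass with incremental averaging (momentum 1/i on batch i)
    leaves each layer's running mean/var equal to the mean of the batch
    statistics seen, after which train- and eval-mode behavior agree.
    """
    bns = [(m, m.momentum) for _, m in model.named_modules()
           if isinstance(m, BatchNorm2d)]
    model.train()
    with no_grad():
        for i, b0 in enumerate(range(0, len(prepared), batch_size), start=1):
            for bn, _ in bns:
                bn.momentum = 1.0 / i
            images = Tensor(np.stack([p[0] for p in prepared[b0 : b0 + batch_size]]))
            model(images)
    for bn, mom in bns:
        bn.momentum = mom
    model.eval()


def _loss_of(model: DOD, batch, cfg: TrainConfig, size: int):
    images = Tensor(np.stack([b[0] for b in batch]))
    outputs = model(images)
    return compute_training_loss(
        outputs, [b[1] for b in batch], model.cfg, cfg.loss_weights,
        topk=cfg.tal_topk, tal_alpha=cfg.tal_alpha, tal_beta=cfg.tal_beta,
        input_size=size,
    )


def train(
    model: DOD,
    train_samples: list,
    config: TrainConfig,
    val_samples: list | None = None,
    checkpoint_path: str | None = None,
    log=lambda s: None,
):
    """Optimize `model`; returns (history, best_state_dict).

    History holds one record per epoch with the learning rate and the
    four per-term losses on train (and validation when given).  The best
    state is the epoch with the lowest validation loss (training loss
    when no validation split is given); non-finite loss aborts.
    """
    if not train_samples:
        raise ValueError("empty training set")
    size = model.cfg.input_size
    rng = np.random.default_rng(config.seed)
    spe = max(1, int(np.ceil(len(train_samples) / config.batch_size)))
    config = replace(config, steps_per_epoch=spe)
    opt = AmsGrad(model.parameters(), config.betas, config.eps,
                  config.loss_weights.weight_decay)
    val_prep = [_prepare(s, size) for s in (val_samples or [])]
    clean_prep = [_prepare(s, size) for s in train_samples]
    history = []
    best = (np.inf, None)
    step = 0
    for epoch in range(config.epochs):
        model.train()
        augmented = _augment(train_samples, epoch, config, rng, size)
        prepared = [_prepare(s, size) for s in augmented]
        order = rng.permutation(len(prepared))
        sums = {"box": 0.0, "cls": 0.0, "dfl": 0.0, "depth": 0.0}
        nb = 0
        lr = lr_at(step, config)
        for b0 in range(0, len(order), config.batch_size):
            batch = [prepared[j] for j in order[b0 : b0 + config.batch_size]]
            lr = lr_at(step, config)
            res = _loss_of(model, batch, config, size)
            total = res["total"]
            if not np.isfinite(total.item()):
                raise RuntimeError(
                    f"diverged at epoch {epoch} step {step}: loss={total.item()} terms={res}"
                )
            model.zero_grad()
            total.backward()
            if config.grad_clip_norm:
                gn = np.sqrt(sum(float((p.grad**2).sum())
                                 for p in opt.params if p.grad is not None))
                if gn > config.grad_clip_norm:
                    scale = config.grad_clip_norm / (gn + 1e-12)
                    for p in opt.params:
                        if p.grad is not None:
                            p.grad *= scale
            opt.step(lr)
            step += 1
            nb += 1
            for k in sums:
                sums[k] += res[k]
        rec = {"epoch": epoch, "lr": lr}
        rec.update({f"train_{k}": v / nb for k, v in sums.items()})
        select_loss = sum(
            getattr(config.loss_weights, k) * rec[f"train_{k}"] for k in sums
        )
        if val_prep:
            recalibrate_bn(model, clean_prep[: 8 * config.batch_size],
                           config.batch_size)
            model.eval()
            vs = {"box": 0.0, "cls": 0.0, "dfl": 0.0, "depth": 0.0}
            vn = 0
            with no_grad():
                for b0 in range(0, len(val_prep), config.batch_size):
                    res = _loss_of(model, val_prep[b0 : b0 + config.batch_size],
                                   config, size)
                    for k in vs:
                        vs[k] += res[k]
                    vn += 1
            rec.update({f"val_{k}": v / vn for k, v in vs.items()})
            select_loss = sum(
                getattr(config.loss_weights, k) * rec[f"val_{k}"] for k in vs
            )
        history.append(rec)
        log(f"epoch {epoch}: lr={lr:.2e} " +
            " ".join(f"{k}={v:.4f}" for k, v in rec.items() if k not in ("epoch", "lr")))
        if select_loss < best[0]:
            best = (select_loss, {k: v.copy() for k, v in model.state_dict().items()})
    if best[1] is not None:
        model.load_state_dict(best[1])
    recalibrate_bn(model, clean_prep, config.batch_size)
    best = (best[0], {k: v.copy() for k, v in model.state_dict().items()})
    if checkpoint_path:
        save_checkpoint(checkpoint_path, model)
    return history, best[1]


def write_history_csv(path, history) -> None:
    if not history:
        return
    keys = list(history[0].keys())
    with open(path, "w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=keys)
        wr.writeheader()
        wr.writerows(history)
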