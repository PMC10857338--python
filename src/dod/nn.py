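"""Layer primitives: modules, 2-D convolution, batch norm, pooling, upsampling.

Convolution is im2col + BLAS matmul with a hand-written backward pass; the
column matrix is cached on the forward tensor's closure so the backward is
two matmuls plus a k×k scatter-add.  All parameters are float32
:class:`~dod.autograd.Tensor` objects with ``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor, is_grad_enabled

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ConvBlock",
    "conv2d",
    "max_pool2d_same",
    "upsample_nearest2x",
]


class Module:
    """Base class with recursive parameter/module discovery by attribute name."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for n, m in self._modules.items():
            yield from m.named_modules(prefix + n + ".")

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        out = {}
        for name, mod in self.named_modules():
            pre = name + "." if name else ""
            for n, p in mod._params.items():
                out[pre + n] = p.data
            for n in getattr(mod, "_buffers", ()):  # running BN stats
                out[pre + n] = getattr(mod, n)
        return out

    def load_state_dict(self, sd: dict) -> None:
        for name, mod in self.named_modules():
            pre = name + "." if name else ""
            for n, p in mod._params.items():
                p.data = np.asarray(sd[pre + n], dtype=np.float32).reshape(p.data.shape)
            for n in getattr(mod, "_buffers", ()):
                setattr(mod, n, np.asarray(sd[pre + n], dtype=np.float32))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel/stride/padding."""
    xd = x.data
    N, C, H, W = xd.shape
    cout, cin, k, k2 = w.data.shape
    if cin != C or k != k2:
        raise ValueError(f"kernel {w.data.shape} incompatible with input {xd.shape}")
    ho = (H + 2 * pad - k) // stride + 1
    wo = (W + 2 * pad - k) // stride + 1
    if ho <= 0 or wo <= 0:
        raise ValueError("invalid conv geometry")
    xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else xd
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * ho * wo, C * k * k
    )
    wmat = w.data.reshape(cout, -1)
    out = cols @ wmat.T
    if b is not None:
        out += b.data
    out_t = out.reshape(N, ho, wo, cout).transpose(0, 3, 1, 2)

    need_x = x.requires_grad
    need_w = w.requires_grad
    need_b = b is not None and b.requires_grad
    if not is_grad_enabled() or not (need_x or need_w or need_b):
        return Tensor(out_t)

    def bw(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * ho * wo, cout)
        if need_w:
            w._accum((gm.T @ cols).reshape(w.data.shape))
        if need_b:
            b._accum(gm.sum(axis=0))
        if need_x:
            dcols = (gm @ wmat).reshape(N, ho, wo, C, k, k)
            dxp = np.zeros_like(xp)
            for ki in range(k):
                for kj in range(k):
                    dxp[:, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride] += (
                        dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
                    )
            x._accum(dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp)

    return Tensor._make(out_t, (x, w) + ((b,) if b is not None else ()), bw)


class Conv2d(Module):
    """Plain convolution (no norm/activation).  Kaiming-uniform init."""

    def __init__(self, cin: int, cout: int, k: int = 1, stride: int = 1,
                 pad: int | None = None, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k = cin, cout, k
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        fan_in = cin * k * k
        bound = np.sqrt(1.0 / fan_in)
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(cout, cin, k, k)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = (
            Tensor(rng.uniform(-bound, bound, size=cout).astype(np.float32), requires_grad=True)
            if bias
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics.

    Small-batch-friendly defaults: eps=1e-3, momentum=0.03 (running stats move
    slowly, matching the update `run = (1-m)·run + m·batch`).
    """

    _buffers = ("running_mean", "running_var")

    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        if self.training:
            mu = xd.mean(axis=(0, 2, 3))
            var = xd.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            n = xd.shape[0] * xd.shape[2] * xd.shape[3]
            unbiased = var * (n / max(n - 1, 1))
            self.running_var = (1 - m) * self.running_var + m * unbiased
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mu[:, None, None]) * invstd[:, None, None]
        out = self.gamma.data[:, None, None] * xhat + self.beta.data[:, None, None]

        gamma, beta = self.gamma, self.beta
        need = x.requires_grad or gamma.requires_grad
        if not is_grad_enabled() or not need:
            return Tensor(out)
        training = self.training

        def bw(g):
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dxhat = g * gamma.data[:, None, None]
                if training:
                    mcount = g.shape[0] * g.shape[2] * g.shape[3]
                    s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                    s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    dx = (dxhat - s1 / mcount - xhat * s2 / mcount) * invstd[:, None, None]
                else:
                    dx = dxhat * invstd[:, None, None]
                x._accum(dx)

        return Tensor._make(out, (x, gamma, beta), bw)


class ConvBlock(Module):
    """Conv → BatchNorm → SiLU, the basic feature-extraction unit.

    Supports post-training quantization hooks: while ``calib`` is a dict
    the block records its output range; when ``act_quant = (scale, zp)``
    the pre-activation map is passed through an int8 quantize–dequantize
    round trip (the SiLU itself stays float).
    """

    def __init__(self, cin: int, cout: int, k: int = 1, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.calib = None
        self.act_quant = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        if self.calib is not None:
            self.calib["lo"] = min(self.calib.get("lo", np.inf), float(y.data.min()))
            self.calib["hi"] = max(self.calib.get("hi", -np.inf), float(y.data.max()))
        if self.act_quant is not None:
            scale, zp = self.act_quant
            q = np.clip(np.round(y.data / scale) + zp, -128, 127)
            y = Tensor(((q - zp) * scale).astype(np.float32))
        return y.silu()


def max_pool2d_same(x: Tensor, k: int) -> Tensor:
    """Stride-1 max pool with same-size output (odd k)."""
    if k % 2 == 0:
        raise ValueError("pool kernel must be odd")
    pad = k // 2
    xd = x.data
    N, C, H, W = xd.shape
    xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    win = sliding_window_view(xp, (k, k), axis=(2, 3)).reshape(N, C, H, W, k * k)
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    if not is_grad_enabled() or not x.requires_grad:
        return Tensor(out)

    def bw(g):
        dxp = np.zeros_like(xp)
        ki, kj = np.divmod(arg, k)
        ii, cc, rr, ww = np.indices(arg.shape, sparse=False)
        np.add.at(dxp, (ii, cc, rr + ki, ww + kj), g)
        x._accum(dxp[:, :, pad : pad + H, pad : pad + W])

    return Tensor._make(out, (x,), bw)


def upsample_nearest2x(x: Tensor) -> Tensor:
    xd = x.data
    N, C, H, W = xd.shape
    out = xd.repeat(2, axis=2).repeat(2, axis=3)
    if not is_grad_enabled() or not x.requires_grad:
        return Tensor(out)

    def bw(g):
        x._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), bw)
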