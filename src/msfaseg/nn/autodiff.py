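"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the segmentation network needs:
broadcast add/mul, matmul, ReLU, sigmoid, 2-D convolution (stride 1 or 2,
"same"-style zero padding), 2-D transposed convolution (stride 2, exact 2x
upsampling), batch normalization, global average pooling, channel
concatenation, dropout and the soft-Dice loss.  Convolutions use cached
im2col/col2im index tables and `np.bincount` scatter-adds, which keeps a
pure-numpy training loop fast enough for CPU-scale experiments.

All arithmetic is float32.  Gradient correctness is established by
finite-difference checks in the test suite, not assumed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "conv2d",
    "conv_transpose2d",
    "batch_norm_2d",
    "global_avg_pool",
    "concat_channels",
    "dropout",
    "soft_dice_loss",
]


class Tensor:
    """A numpy array plus gradient bookkeeping for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor, seeding with ones."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topo sort; deep graphs would blow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product: (N, K) @ (K, M)."""
    data = a.data @ b.data

    def backward(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _make(data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    data = x.data * mask

    def backward(g):
        x._accumulate(g * mask)

    return _make(data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic, clipped away from exact 0/1 so downstream
    # open-interval contracts and loss ratios stay well defined in float32
    d = x.data
    out = np.empty_like(d)
    pos = d >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    ex = np.exp(d[~pos])
    out[~pos] = ex / (1.0 + ex)
    np.clip(out, 1e-6, 1.0 - 1e-6, out=out)

    def backward(g):
        x._accumulate(g * out * (1.0 - out))

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# im2col machinery (indices cached per shape signature)

_COL_CACHE: dict[tuple, tuple] = {}


def _col_indices(C, H, W, kh, kw, stride, pad):
    key = (C, H, W, kh, kw, stride, pad)
    hit = _COL_CACHE.get(key)
    if hit is not None:
        return hit
    out_h = (H + 2 * pad - kh) // stride + 1
    out_w = (W + 2 * pad - kw) // stride + 1
    i0 = np.tile(np.repeat(np.arange(kh), kw), C)
    j0 = np.tile(np.arange(kw), kh * C)
    i1 = stride * np.repeat(np.arange(out_h), out_w)
    j1 = stride * np.tile(np.arange(out_w), out_h)
    i = i0[:, None] + i1[None, :]
    j = j0[:, None] + j1[None, :]
    k = np.repeat(np.arange(C), kh * kw)[:, None]
    Hp, Wp = H + 2 * pad, W + 2 * pad
    lin = (k * (Hp * Wp) + i * Wp + j).ravel()  # flat scatter targets, per sample
    res = (k, i, j, lin, out_h, out_w, Hp, Wp)
    _COL_CACHE[key] = res
    return res


def _im2col(x, kh, kw, stride, pad):
    N, C, H, W = x.shape
    out_h = (H + 2 * pad - kh) // stride + 1
    out_w = (W + 2 * pad - kw) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, out_h, out_w, kh, kw)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(N, C * kh * kw,
                                                   out_h * out_w)
    return np.ascontiguousarray(cols), out_h, out_w


def _col2im(cols, shape, kh, kw, stride, pad):
    """Scatter-add columns back to an image of `shape` = (N, C, H, W)."""
    N, C, H, W = shape
    _, _, _, lin, _, _, Hp, Wp = _col_indices(C, H, W, kh, kw, stride, pad)
    per = C * Hp * Wp
    offs = (np.arange(N, dtype=np.int64) * per)[:, None]
    idx = (lin[None, :] + offs).ravel()
    flat = np.bincount(idx, weights=cols.reshape(N, -1).ravel(), minlength=N * per)
    xpad = flat.reshape(N, C, Hp, Wp).astype(np.float32)
    if pad:
        return xpad[:, :, pad:-pad, pad:-pad]
    return xpad


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           pad: int = 1) -> Tensor:
    """2-D convolution. weight: (F, C*kh*kw) with kernel (kh, kw) implied square.

    The kernel size is recovered from weight.shape[1] / x channels; callers in
    this package only use 3x3 and 1x1 kernels.
    """
    N, C, H, W = x.data.shape
    F, CK = weight.data.shape
    k2 = CK // C
    kh = kw = int(round(k2 ** 0.5))
    if kh * kw * C != CK:
        raise ValueError(f"weight columns {CK} not divisible into {C} x k^2")
    pointwise = kh == 1 and stride == 1 and pad == 0
    if pointwise:  # 1x1 conv: plain channel mixing, no patch extraction
        cols, out_h, out_w = x.data.reshape(N, C, H * W), H, W
    else:
        cols, out_h, out_w = _im2col(x.data, kh, kw, stride, pad)
    out = np.matmul(weight.data, cols)  # (N, F, L)
    if bias is not None:
        out += bias.data[None, :, None]
    out = out.reshape(N, F, out_h, out_w)

    def backward(g):
        gf = g.reshape(N, F, -1)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gf.sum(axis=(0, 2)))
        if weight.requires_grad:
            dw = np.matmul(gf, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(dw)
        if x.requires_grad or x._parents:
            dcols = np.matmul(weight.data.T, gf)  # (N, CK, L)
            if pointwise:
                x._accumulate(dcols.reshape(x.data.shape))
            else:
                x._accumulate(_col2im(dcols, x.data.shape, kh, kw, stride, pad))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out, parents, backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None,
                     out_hw: tuple[int, int]) -> Tensor:
    """3x3 stride-2 transposed convolution producing exactly `out_hw` = (2H, 2W).

    weight: (Cin, Cout*9).  Implemented as the adjoint of a 3x3 stride-2
    convolution from the output grid back to the input grid.
    """
    N, Cin, H, W = x.data.shape
    Ho, Wo = out_hw
    CoK = weight.data.shape[1]
    Cout = CoK // 9
    xf = x.data.reshape(N, Cin, H * W)
    cols = np.matmul(weight.data.T, xf)  # (N, Cout*9, H*W)
    out = _col2im(cols, (N, Cout, Ho, Wo), 3, 3, 2, 1)
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        gcols, _, _ = _im2col(g, 3, 3, 2, 1)  # (N, Cout*9, H*W)
        if weight.requires_grad:
            dw = np.matmul(xf, gcols.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(dw)
        if x.requires_grad or x._parents:
            dx = np.matmul(weight.data, gcols).reshape(N, Cin, H, W)
            x._accumulate(dx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out, parents, backward)


def batch_norm_2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean,
                  running_var, momentum: float, eps: float,
                  training: bool) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    `running_mean`/`running_var` are plain float32 arrays mutated in place
    when training (exponential moving average with `momentum`).
    """
    N, C, H, W = x.data.shape
    m = N * H * W
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))  # unbiased for EMA
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gi = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
            if training:
                gm = g.mean(axis=(0, 2, 3))[None, :, None, None]
                gxm = (g * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
                dx = gi * (g - gm - xhat * gxm)
            else:
                dx = gi * g
            x._accumulate(dx)

    return _make(out, (x, gamma, beta), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C): per-channel spatial mean."""
    N, C, H, W = x.data.shape
    data = x.data.mean(axis=(2, 3))

    def backward(g):
        x._accumulate(np.broadcast_to(g[:, :, None, None] / (H * W),
                                      x.data.shape).astype(np.float32))

    return _make(data, (x,), backward)


def channel_gate(x: Tensor, s: Tensor) -> Tensor:
    """Multiply (N, C, H, W) feature map by per-channel gate (N, C)."""
    data = x.data * s.data[:, :, None, None]

    def backward(g):
        x._accumulate(g * s.data[:, :, None, None])
        s._accumulate((g * x.data).sum(axis=(2, 3)))

    return _make(data, (x, s), backward)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.data.shape[1] for t in tensors]
    bounds = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, bounds[:-1], bounds[1:]):
            t._accumulate(g[:, a:b])

    return _make(data, tuple(tensors), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep).astype(np.float32) / keep
    data = x.data * mask

    def backward(g):
        x._accumulate(g * mask)

    return _make(data, (x,), backward)


def soft_dice_loss(pred: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    """Soft Dice loss, mean over the batch.

    loss_n = 1 - (2 * sum(p*t) + eps) / (sum(t) + sum(p) + eps), with sums over
    each sample's pixels; differentiable in `pred`.
    """
    t = np.asarray(target, dtype=np.float32)
    if t.shape != pred.data.shape:
        raise ValueError(f"shape mismatch: pred {pred.data.shape} vs target {t.shape}")
    N = pred.data.shape[0]
    axes = tuple(range(1, pred.data.ndim))
    inter = (pred.data * t).sum(axis=axes)
    denom = t.sum(axis=axes) + pred.data.sum(axis=axes) + eps
    per = 1.0 - (2.0 * inter + eps) / denom
    data = np.float32(per.mean())

    def backward(g):
        # d/dp [ -(2*S_pt+eps)/D ] with D depending on sum(p)
        num = (2.0 * inter + eps)
        dp = -(2.0 * t * denom[(...,) + (None,) * (t.ndim - 1)]
               - num[(...,) + (None,) * (t.ndim - 1)]) \
            / (denom ** 2)[(...,) + (None,) * (t.ndim - 1)]
        pred._accumulate((g * dp / N).astype(np.float32))

    return _make(data, (pred,), backward)
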