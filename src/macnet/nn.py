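"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The decoding model in this package is small (~112 K parameters) and built
from a handful of primitives: stride-1 2-D convolution, batch normalization,
average pooling, softmax attention, sigmoid gates and a cross-entropy head.
This module implements exactly those primitives as a tape-based autodiff
engine.  Convolutions are lowered to im2col + GEMM so the heavy lifting stays
inside BLAS; their input gradients go through a GEMM + col2im scatter (a
short Python loop over kernel taps, never an element loop).

Dtype policy: the graph preserves the dtype of its inputs.  Training uses
float32 for speed; correctness tests run the same code in float64.

Every primitive's backward pass is checked against central differences in
the test suite.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Tensor", "Parameter", "backward"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph: an ndarray plus a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self._grad_owned = False

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        # first contribution borrows the array; later ones copy-on-write
        # (several backward rules hand the same buffer to multiple parents)
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)


class Parameter(Tensor):
    """A leaf tensor holding learnable weights."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def backward(loss: Tensor) -> None:
    """Backpropagate from a scalar loss through the tape."""
    if loss.data.size != 1:
        raise ValueError("backward() expects a scalar loss")
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:
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
    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)
            node._backward = None  # free closures as we go


# ---------------------------------------------------------------------------
# elementwise / shape primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    # python-scalar fast path (also keeps float32 graphs in float32)
    if isinstance(b, (int, float)):
        a = _as_tensor(a)
        b = float(b)  # plain python float: no dtype promotion
        out_data = a.data + b

        def bwd_s(g):
            a._accumulate(g)

        return _node(out_data, (a,), bwd_s)
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), bwd)


def mul(a, b) -> Tensor:
    if isinstance(b, (int, float)):
        a = _as_tensor(a)
        b = float(b)
        out_data = a.data * b

        def bwd_s(g):
            a._accumulate(g * b)

        return _node(out_data, (a,), bwd_s)
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), bwd)


def matmul(a, b) -> Tensor:
    """Batched matrix product with NumPy broadcasting over leading axes."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = np.matmul(a.data, b.data)

    def bwd(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _node(out_data, (a, b), bwd)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    out_data = a.data.reshape(shape)

    def bwd(g):
        a._accumulate(g.reshape(a.data.shape))

    return _node(out_data, (a,), bwd)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
        axes = tuple(axes[0])
    inv = np.argsort(axes)
    out_data = a.data.transpose(axes)

    def bwd(g):
        a._accumulate(g.transpose(inv))

    return _node(out_data, (a,), bwd)


def concat(tensors, axis: int) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return _node(out_data, tuple(tensors), bwd)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    n = a.data.size if axis is None else math.prod(
        a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))
    )

    def bwd(g):
        if not keepdims and axis is not None:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape) / n)

    return _node(out_data, (a,), bwd)


def amax(a, axis, keepdims: bool = False) -> Tensor:
    """Max over one or more axes; ties route the gradient to the first hit."""
    a = _as_tensor(a)
    axes = axis if isinstance(axis, tuple) else (axis,)
    axes = tuple(ax % a.data.ndim for ax in axes)
    if len(axes) == 1:
        ax = axes[0]
        idx = a.data.argmax(axis=ax)
        idx_k = np.expand_dims(idx, ax)
        out_k = np.take_along_axis(a.data, idx_k, axis=ax)
        out_data = out_k if keepdims else np.squeeze(out_k, axis=ax)

        def bwd1(g):
            dx = np.zeros_like(a.data)
            gk = g if keepdims else np.expand_dims(g, ax)
            np.put_along_axis(dx, idx_k, gk, axis=ax)
            a._accumulate(dx)

        return _node(out_data, (a,), bwd1)
    # move reduced axes to the end and flatten them
    keep = tuple(i for i in range(a.data.ndim) if i not in axes)
    perm = keep + axes
    moved = a.data.transpose(perm)
    lead = moved.shape[: len(keep)]
    red = math.prod(moved.shape[len(keep):]) if axes else 1
    flat = moved.reshape(lead + (red,))
    idx = flat.argmax(axis=-1)
    out_flat = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    if keepdims:
        out_data = out_flat.reshape(
            tuple(1 if i in axes else s for i, s in enumerate(a.data.shape))
        )
    else:
        out_data = out_flat

    def bwd(g):
        gf = g.reshape(lead)
        gflat = np.zeros(lead + (red,), dtype=a.data.dtype)
        np.put_along_axis(gflat, idx[..., None], gf[..., None], axis=-1)
        gmoved = gflat.reshape(moved.shape)
        a._accumulate(gmoved.transpose(np.argsort(perm)))

    return _node(out_data, (a,), bwd)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def bwd(g):
        a._accumulate(g * mask)

    return _node(out_data, (a,), bwd)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _node(out_data, (a,), bwd)


def square(a) -> Tensor:
    a = _as_tensor(a)

    def bwd(g):
        a._accumulate(2.0 * g * a.data)

    return _node(a.data * a.data, (a,), bwd)


def safe_log(a, eps: float = 1e-6) -> Tensor:
    """log(max(x, eps)); gradient is zero on the clamped region."""
    a = _as_tensor(a)
    clamped = np.maximum(a.data, eps)
    out_data = np.log(clamped)
    mask = a.data > eps

    def bwd(g):
        a._accumulate(g * mask / clamped)

    return _node(out_data, (a,), bwd)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accumulate(out_data * (g - dot))

    return _node(out_data, (a,), bwd)


def dropout(a, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    a = _as_tensor(a)
    if not training or p <= 0.0:
        return a
    keep = (rng.random(a.data.shape) >= p).astype(a.data.dtype) / (1.0 - p)
    return mul(a, Tensor(keep))


# ---------------------------------------------------------------------------
# convolution / pooling / batchnorm
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int):
    """[B,Cin,H,W] -> col [B, Ho*Wo, Cin*kh*kw] (stride 1, no padding)."""
    B, Cin, H, W = x.shape
    Ho, Wo = H - kh + 1, W - kw + 1
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    col = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B, Ho * Wo, Cin * kh * kw
    )
    return col, Ho, Wo


def conv2d(x, weight, bias=None, padding=(0, 0)) -> Tensor:
    """Stride-1 'valid' 2-D convolution (cross-correlation) with zero padding.

    x: [B, Cin, H, W]; weight: [F, Cin, kh, kw]; bias: [F] or None.
    Large-kernel/many-filter cases are lowered to im2col + GEMM; small
    F·Cin·kh·kw cases (e.g. the CBAM 7×7 gate conv) use a tap loop that
    avoids the big im2col buffer.
    """
    x, weight = _as_tensor(x), _as_tensor(weight)
    if bias is not None:
        bias = _as_tensor(bias)
    ph, pw = padding
    F, Cin, kh, kw = weight.data.shape
    if F * Cin * kh * kw <= 256 and kh * kw > 1:
        return _conv2d_taploop(x, weight, bias, padding)
    xd = x.data
    if ph or pw:
        xd = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    B = xd.shape[0]
    col, Ho, Wo = _im2col(xd, kh, kw)
    wmat = weight.data.reshape(F, Cin * kh * kw)
    out = np.matmul(col, wmat.T)  # [B, Ho*Wo, F]
    if bias is not None:
        out += bias.data
    out_data = np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(B, F, Ho, Wo)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        gmat = np.ascontiguousarray(g.reshape(B, F, Ho * Wo).transpose(0, 2, 1))
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=(0, 1)))
        if weight.requires_grad:
            gw = np.matmul(gmat.transpose(0, 2, 1), col).sum(axis=0)
            weight._accumulate(gw.reshape(weight.data.shape))
        if x.requires_grad:
            dcol = np.matmul(gmat, wmat)  # [B, Ho*Wo, Cin*kh*kw]
            dcol = dcol.reshape(B, Ho, Wo, Cin, kh, kw)
            dxp = np.zeros_like(xd)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + Ho, j:j + Wo] += dcol[:, :, :, :, i, j].transpose(
                        0, 3, 1, 2
                    )
            if ph or pw:
                dxp = dxp[:, :, ph:dxp.shape[2] - ph or None, pw:dxp.shape[3] - pw or None]
            x._accumulate(dxp)

    return _node(out_data, parents, bwd)


def _conv2d_taploop(x: Tensor, weight: Tensor, bias, padding) -> Tensor:
    """Memory-light conv path: loop over kernel taps with slice arithmetic."""
    ph, pw = padding
    F, Cin, kh, kw = weight.data.shape
    xd = x.data
    if ph or pw:
        xd = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    B, _, Hp, Wp = xd.shape
    Ho, Wo = Hp - kh + 1, Wp - kw + 1
    w = weight.data
    out_data = np.zeros((B, F, Ho, Wo), dtype=xd.dtype)
    for f in range(F):
        acc = out_data[:, f]
        for c in range(Cin):
            for i in range(kh):
                for j in range(kw):
                    acc += float(w[f, c, i, j]) * xd[:, c, i:i + Ho, j:j + Wo]
        if bias is not None:
            acc += float(bias.data[f])
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.empty_like(weight.data)
            for f in range(F):
                for c in range(Cin):
                    for i in range(kh):
                        for j in range(kw):
                            gw[f, c, i, j] = np.vdot(
                                g[:, f], xd[:, c, i:i + Ho, j:j + Wo]
                            )
            weight._accumulate(gw)
        if x.requires_grad:
            dxp = np.zeros_like(xd)
            for f in range(F):
                gf = g[:, f]
                for c in range(Cin):
                    for i in range(kh):
                        for j in range(kw):
                            dxp[:, c, i:i + Ho, j:j + Wo] += float(w[f, c, i, j]) * gf
            if ph or pw:
                dxp = dxp[:, :, ph:Hp - ph or None, pw:Wp - pw or None]
            x._accumulate(dxp)

    return _node(out_data, parents, bwd)


def avg_pool2d(x, kernel: tuple[int, int], stride: tuple[int, int]) -> Tensor:
    """Average pooling; kernel/stride given as (kh, kw)/(sh, sw)."""
    x = _as_tensor(x)
    kh, kw = kernel
    sh, sw = stride
    B, C, H, W = x.data.shape
    Ho = (H - kh) // sh + 1
    Wo = (W - kw) // sw + 1
    v = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(2, 3))
    v = v[:, :, ::sh, ::sw]  # [B,C,Ho,Wo,kh,kw]
    out_data = v.mean(axis=(-1, -2))
    scale = 1.0 / (kh * kw)

    def bwd(g):
        dx = np.zeros_like(x.data)
        for i in range(Ho):
            for j in range(Wo):
                dx[:, :, i * sh:i * sh + kh, j * sw:j * sw + kw] += (
                    g[:, :, i, j][:, :, None, None] * scale
                )
        x._accumulate(dx)

    return _node(out_data, (x,), bwd)


def batch_norm(x, running_mean, running_var, training: bool,
               momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Affine-free batch normalization over (B, H, W) per feature map.

    running_mean/running_var are plain ndarrays updated in place in training
    mode (population statistics for evaluation).
    """
    x = _as_tensor(x)
    axes = (0, 2, 3)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        n = x.data.size // x.data.shape[1]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        unbiased = var * (n / max(n - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    mu_b = mu[None, :, None, None]
    inv_b = inv[None, :, None, None]
    y = (x.data - mu_b) * inv_b

    def bwd(g):
        if training:
            gm = g.mean(axis=axes, keepdims=True)
            gy = (g * y).mean(axis=axes, keepdims=True)
            x._accumulate(inv_b * (g - gm - y * gy))
        else:
            x._accumulate(g * inv_b)

    return _node(y.astype(x.data.dtype, copy=False), (x,), bwd)


def cross_entropy_with_logits(logits, labels) -> Tensor:
    """Mean cross-entropy of integer labels under softmax(logits).

    logits: [B, M]; labels: int array [B].  Returns a scalar Tensor.
    """
    logits = _as_tensor(logits)
    labels = np.asarray(labels)
    B = logits.data.shape[0]
    shifted = logits.data - logits.data.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1))
    nll = logz - shifted[np.arange(B), labels]
    out_data = np.asarray(nll.mean(), dtype=logits.data.dtype)
    probs = np.exp(shifted) / np.exp(shifted).sum(axis=1, keepdims=True)

    def bwd(g):
        d = probs.copy()
        d[np.arange(B), labels] -= 1.0
        logits._accumulate(g * d / B)

    return _node(out_data, (logits,), bwd)
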