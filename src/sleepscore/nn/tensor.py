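"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape-based engine in the style of autograd/micrograd, sized for the
small CNNs this package trains on CPU. Two properties matter here:

* every primitive's vector-Jacobian product (VJP) is itself written in
  terms of these primitives, so gradients are differentiable — calling
  :func:`grad` with ``create_graph=True`` yields a gradient you can
  backpropagate through again (needed for the WGAN-GP gradient penalty,
  whose loss contains the norm of an input gradient);
* convolution is expressed as ``im2col`` + matrix multiply, whose
  backward pass (``col2im``) is the transpose linear map, so conv and
  its double-backward reduce to BLAS calls.

Arrays keep whatever float dtype they are given; the networks in this
package use float32, the finite-difference tests float64.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "Tensor", "no_grad", "grad",
    "add", "mul", "matmul", "reshape", "transpose", "tsum", "mean",
    "exp", "log", "sqrt", "relu", "leaky_relu", "sigmoid", "tanh",
    "broadcast_to", "im2col", "col2im", "upsample_nearest", "sumpool",
    "maxpool2", "stop_gradient",
]

_grad_enabled = True


class no_grad:
    """Context manager that suspends graph recording."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


class Tensor:
    __slots__ = ("data", "requires_grad", "parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.parents: list[tuple["Tensor", Callable]] | None = None

    # -- introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data.item())

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"

    # -- operators ----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(_wrap(other)))

    def __rsub__(self, other):
        return add(_wrap(other), neg(self))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data: np.ndarray, parents: Sequence[tuple[Tensor, Callable]]) -> Tensor:
    out = Tensor(data)
    if _grad_enabled:
        recorded = [(p, vjp) for p, vjp in parents if p.requires_grad]
        if recorded:
            out.requires_grad = True
            out.parents = recorded
    return out


def _unbroadcast(g: Tensor, shape: tuple[int, ...]) -> Tensor:
    """Sum ``g`` over the axes numpy broadcasting expanded, back to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.data + b.data, [
        (a, lambda g: _unbroadcast(g, a.shape)),
        (b, lambda g: _unbroadcast(g, b.shape)),
    ])


def neg(a: Tensor) -> Tensor:
    return _make(-a.data, [(a, lambda g: neg(g))])


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.data * b.data, [
        (a, lambda g: _unbroadcast(mul(g, b), a.shape)),
        (b, lambda g: _unbroadcast(mul(g, a), b.shape)),
    ])


def div(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.data / b.data, [
        (a, lambda g: _unbroadcast(div(g, b), a.shape)),
        (b, lambda g: _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape)),
    ])


def power(a: Tensor, p: float) -> Tensor:
    p = float(p)
    return _make(a.data ** p, [
        (a, lambda g: mul(g, mul(Tensor(np.asarray(p, dtype=a.dtype)), power(a, p - 1.0)))),
    ])


def matmul(a: Tensor, b: Tensor) -> Tensor:
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    return _make(a.data @ b.data, [
        (a, lambda g: matmul(g, transpose(b))),
        (b, lambda g: matmul(transpose(a), g)),
    ])


def transpose(a: Tensor, axes: tuple[int, ...] | None = None) -> Tensor:
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), [(a, lambda g: transpose(g, inv))])


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    old = a.shape
    return _make(a.data.reshape(shape), [(a, lambda g: reshape(g, old))])


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    in_shape = a.shape

    def vjp(g: Tensor) -> Tensor:
        if axis is None:
            return broadcast_to(reshape(g, (1,) * len(in_shape)), in_shape)
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        axes = tuple(ax % len(in_shape) for ax in axes)
        if not keepdims:
            kshape = tuple(1 if i in axes else n for i, n in enumerate(in_shape))
            g = reshape(g, kshape)
        return broadcast_to(g, in_shape)

    return _make(a.data.sum(axis=axis, keepdims=keepdims), [(a, vjp)])


def broadcast_to(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    orig = a.shape
    return _make(np.broadcast_to(a.data, shape).copy(), [
        (a, lambda g: _unbroadcast(g, orig)),
    ])


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims),
               Tensor(np.asarray(1.0 / n, dtype=a.dtype)))


# NOTE: vjps below recompute the forward value instead of capturing the
# output tensor — capturing it would create a closure reference cycle
# that keeps whole graphs alive until the cyclic GC runs.

def exp(a: Tensor) -> Tensor:
    return _make(np.exp(a.data), [(a, lambda g: mul(g, exp(a)))])


def log(a: Tensor) -> Tensor:
    return _make(np.log(a.data), [(a, lambda g: div(g, a))])


def sqrt(a: Tensor) -> Tensor:
    return _make(np.sqrt(a.data), [
        (a, lambda g: div(mul(g, Tensor(np.asarray(0.5, a.dtype))), sqrt(a))),
    ])


def relu(a: Tensor) -> Tensor:
    mask = (a.data > 0).astype(a.dtype)
    return _make(a.data * mask, [(a, lambda g: mul(g, Tensor(mask)))])


def leaky_relu(a: Tensor, alpha: float = 0.2) -> Tensor:
    slope = np.where(a.data > 0, a.dtype.type(1), a.dtype.type(alpha))
    return _make(a.data * slope, [(a, lambda g: mul(g, Tensor(slope)))])


def sigmoid(a: Tensor) -> Tensor:
    z = np.clip(a.data, -60.0, 60.0)  # avoid float32 exp overflow; sigmoid saturates anyway
    val = (1.0 / (1.0 + np.exp(-z))).astype(a.dtype)

    def vjp(g: Tensor) -> Tensor:
        s = sigmoid(a)
        one = Tensor(np.asarray(1.0, a.dtype))
        return mul(g, mul(s, add(one, neg(s))))

    return _make(val, [(a, vjp)])


def tanh(a: Tensor) -> Tensor:
    def vjp(g: Tensor) -> Tensor:
        t = tanh(a)
        one = Tensor(np.asarray(1.0, a.dtype))
        return mul(g, add(one, neg(mul(t, t))))

    return _make(np.tanh(a.data), [(a, vjp)])


def stop_gradient(a: Tensor) -> Tensor:
    return Tensor(a.data)


# ---------------------------------------------------------------------
# image-shaped linear primitives (NHWC layout)
# ---------------------------------------------------------------------

def _conv_out_hw(H, W, kh, kw, stride, pad):
    return (H + 2 * pad - kh) // stride + 1, (W + 2 * pad - kw) // stride + 1


def _im2col_data(x: np.ndarray, kh, kw, stride, pad) -> np.ndarray:
    N, H, W, C = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    OH, OW = _conv_out_hw(H, W, kh, kw, stride, pad)
    # gather per kernel offset: kh*kw large block copies beat one strided copy
    out = np.empty((N, OH, OW, kh, kw, C), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, :, i, j, :] = x[:, i:i + stride * OH:stride,
                                      j:j + stride * OW:stride, :]
    return out.reshape(N * OH * OW, kh * kw * C)


def _col2im_data(cols: np.ndarray, x_shape, kh, kw, stride, pad) -> np.ndarray:
    N, H, W, C = x_shape
    OH, OW = _conv_out_hw(H, W, kh, kw, stride, pad)
    cols6 = cols.reshape(N, OH, OW, kh, kw, C)
    xp = np.zeros((N, H + 2 * pad, W + 2 * pad, C), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, i:i + stride * OH:stride, j:j + stride * OW:stride, :] += \
                cols6[:, :, :, i, j, :]
    if pad:
        xp = xp[:, pad:pad + H, pad:pad + W, :]
    return np.ascontiguousarray(xp)


def im2col(a: Tensor, kh: int, kw: int, stride: int = 1, pad: int = 0) -> Tensor:
    """Unfold NHWC windows into rows of a (N*OH*OW, kh*kw*C) matrix."""
    shape = a.shape
    return _make(_im2col_data(a.data, kh, kw, stride, pad), [
        (a, lambda g: col2im(g, shape, kh, kw, stride, pad)),
    ])


def col2im(a: Tensor, x_shape, kh: int, kw: int, stride: int = 1, pad: int = 0) -> Tensor:
    """Transpose of :func:`im2col`: scatter-add window rows back to NHWC."""
    return _make(_col2im_data(a.data, x_shape, kh, kw, stride, pad), [
        (a, lambda g: im2col(g, kh, kw, stride, pad)),
    ])


def upsample_nearest(a: Tensor, factor: int = 2) -> Tensor:
    N, H, W, C = a.shape
    data = np.repeat(np.repeat(a.data, factor, axis=1), factor, axis=2)
    return _make(data, [(a, lambda g: sumpool(g, factor))])


def sumpool(a: Tensor, factor: int = 2) -> Tensor:
    N, H, W, C = a.shape
    if H % factor or W % factor:
        raise ValueError(f"spatial dims {H}x{W} not divisible by pool factor {factor}")
    data = a.data.reshape(N, H // factor, factor, W // factor, factor, C).sum(axis=(2, 4))
    return _make(data, [(a, lambda g: upsample_nearest(g, factor))])


def crop_hw(a: Tensor, H2: int, W2: int) -> Tensor:
    """Keep the top-left H2 x W2 spatial region of an NHWC tensor."""
    N, H, W, C = a.shape
    return _make(np.ascontiguousarray(a.data[:, :H2, :W2, :]), [
        (a, lambda g: pad_hw(g, H, W)),
    ])


def pad_hw(a: Tensor, H2: int, W2: int) -> Tensor:
    """Zero-pad an NHWC tensor at the bottom/right to H2 x W2."""
    N, H, W, C = a.shape
    return _make(
        np.pad(a.data, ((0, 0), (0, H2 - H), (0, W2 - W), (0, 0))),
        [(a, lambda g: crop_hw(g, H, W))],
    )


def maxpool2(a: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; one winner per window (first on ties)."""
    N, H, W, C = a.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {H}x{W}")
    r = a.data.reshape(N, H // 2, 2, W // 2, 2, C)
    quad = r.transpose(0, 1, 3, 5, 2, 4).reshape(N, H // 2, W // 2, C, 4)
    idx = quad.argmax(axis=-1)
    out = np.take_along_axis(quad, idx[..., None], axis=-1)[..., 0]
    onehot = np.zeros_like(quad)
    np.put_along_axis(onehot, idx[..., None], 1.0, axis=-1)
    mask = (
        onehot.reshape(N, H // 2, W // 2, C, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(N, H, W, C)
    )
    return _make(out, [
        (a, lambda g: mul(upsample_nearest(g, 2), Tensor(mask))),
    ])


# ---------------------------------------------------------------------
# reverse pass
# ---------------------------------------------------------------------

def _topo(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        if node.parents:
            for p, _ in node.parents:
                stack.append((p, False))
    return order


def grad(
    output: Tensor,
    wrt: Sequence[Tensor],
    grad_output: Tensor | np.ndarray | None = None,
    create_graph: bool = False,
) -> list[Tensor]:
    """Gradients of a scalar (or seeded) output w.r.t. each tensor in ``wrt``.

    With ``create_graph=True`` the returned gradients carry their own
    tape and can be differentiated again.
    """
    global _grad_enabled
    if grad_output is None:
        if output.size != 1:
            raise ValueError("grad of a non-scalar output needs grad_output")
        grad_output = Tensor(np.ones_like(output.data))
    elif not isinstance(grad_output, Tensor):
        grad_output = Tensor(np.asarray(grad_output, dtype=output.dtype))

    prev = _grad_enabled
    _grad_enabled = bool(create_graph)
    try:
        grads: dict[int, Tensor] = {id(output): grad_output}
        for node in reversed(_topo(output)):
            g = grads.get(id(node))
            if g is None or not node.parents:
                continue
            for parent, vjp in node.parents:
                if not parent.requires_grad:
                    continue
                pg = vjp(g)
                acc = grads.get(id(parent))
                grads[id(parent)] = pg if acc is None else add(acc, pg)
        out = []
        for w in wrt:
            g = grads.get(id(w))
            if g is None:
                g = Tensor(np.zeros_like(w.data))
            out.append(g)
        return out
    finally:
        _grad_enabled = prev
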