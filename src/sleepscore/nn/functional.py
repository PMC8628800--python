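"""Network-level operations composed from the autodiff primitives.

Layout convention is NHWC throughout; a grayscale batch is
``(N, H, W, 1)`` in ``[0, 1]``.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


def conv2d(x: Tensor, w: Tensor, b: Tensor, *, kernel: int = 3,
           stride: int = 1, pad: int = 1) -> Tensor:
    """3x3-style convolution via im2col + GEMM.

    ``w`` is stored flattened as ``(kernel*kernel*C_in, C_out)``; ``b`` is
    ``(C_out,)``.
    """
    N, H, W, C = x.shape
    OH, OW = T._conv_out_hw(H, W, kernel, kernel, stride, pad)
    cols = T.im2col(x, kernel, kernel, stride, pad)
    out = T.matmul(cols, w) + b
    return T.reshape(out, (N, OH, OW, w.shape[1]))


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    return T.matmul(x, w) + b


def flatten(x: Tensor) -> Tensor:
    n = x.shape[0]
    return T.reshape(x, (n, int(np.prod(x.shape[1:]))))


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep).astype(x.dtype) / x.dtype.type(keep)
    return x * Tensor(mask)


def softmax(logits: Tensor) -> Tensor:
    shift = Tensor(logits.data.max(axis=1, keepdims=True))  # constant, stability only
    e = T.exp(logits - shift)
    return e / e.sum(axis=1, keepdims=True)


def one_hot(labels: np.ndarray, n_classes: int, dtype=np.float32) -> np.ndarray:
    out = np.zeros((len(labels), n_classes), dtype=dtype)
    out[np.arange(len(labels)), labels] = 1
    return out


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray,
                          eps: float = 1e-7) -> Tensor:
    """Mean cross-entropy of softmax(logits) against one-hot targets."""
    p = softmax(logits)
    logp = T.log(p + Tensor(np.asarray(eps, dtype=logits.dtype)))
    return T.neg(T.mean(T.tsum(logp * Tensor(onehot), axis=1)))


def he_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...],
            dtype=np.float32) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)
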