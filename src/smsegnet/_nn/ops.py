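"""Reverse-mode autodiff on NumPy arrays for the operations the network needs.

A :class:`Tensor` wraps an ``(N, C, H, W)`` float array and records the
operation that produced it; calling :meth:`Tensor.backward` on a scalar loss
accumulates gradients into every reachable parameter.  Only the handful of
operations the architecture uses are implemented: stride-1 shape-preserving
convolution (1x1 and 3x3 kernels), ReLU, 2x2 max pooling with argmax
recording, index-based unpooling, nearest-neighbour x2 upsampling, channel
concatenation, and fused softmax cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Tensor", "PoolingIndices",
    "conv2d", "relu", "max_pool_with_indices", "max_unpool", "upsample2",
    "concat", "softmax", "softmax_cross_entropy", "cross_entropy",
]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float32)  # float64 kept for gradient checks
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g) -> None:
        self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative post-order; graphs can be deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


@dataclass(frozen=True)
class PoolingIndices:
    """Argmax positions recorded by one 2x2 max-pooling step.

    ``flat`` stores, per pooled cell and channel, the window-local index in
    row-major order (0: top-left, 1: top-right, 2: bottom-left,
    3: bottom-right); ties take the first maximum in that order.
    ``source_shape`` is the pre-pooling (height, width).
    """

    flat: np.ndarray                # (N, C, h, w) ints in {0,1,2,3}
    source_shape: tuple[int, int]

    @property
    def pooled_shape(self) -> tuple[int, int]:
        return self.flat.shape[2], self.flat.shape[3]

    @property
    def offsets(self) -> np.ndarray:
        """(row, col) offsets within each 2x2 window, shape (N, C, h, w, 2)."""
        return np.stack([self.flat // 2, self.flat % 2], axis=-1)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1, zero-padded (shape-preserving) 2D convolution.

    ``w`` has shape (out, in, k, k) with k in {1, 3}; ``b`` has shape (out,).
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    n, c, h, wd = x.shape
    o, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"conv2d: input has {c} channels, kernel expects {ci}")
    if kh != kw or kh not in (1, 3):
        raise ValueError("conv2d supports 1x1 and 3x3 kernels only")
    p = kh // 2
    xd, wdta = x.data, w.data
    if kh == 1:
        y = np.tensordot(xd, wdta[:, :, 0, 0], axes=([1], [1]))  # (N,H,W,O)
    else:
        xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)))
        y = np.zeros((n, h, wd, o), dtype=xd.dtype)
        for di in range(kh):
            for dj in range(kw):
                y += np.tensordot(xp[:, :, di:di + h, dj:dj + wd],
                                  wdta[:, :, di, dj], axes=([1], [1]))
    y = np.ascontiguousarray(y.transpose(0, 3, 1, 2)) + b.data[None, :, None, None]
    out = Tensor(y, parents=(x, w, b))

    def backward(gy):
        if b.requires_grad:
            b._accumulate(gy.sum(axis=(0, 2, 3)))
        if kh == 1:
            if w.requires_grad:
                gw = np.tensordot(gy, xd, axes=([0, 2, 3], [0, 2, 3]))
                w._accumulate(gw[:, :, None, None])
            gx = np.tensordot(gy, wdta[:, :, 0, 0], axes=([1], [0]))
            x._accumulate(np.ascontiguousarray(gx.transpose(0, 3, 1, 2)))
        else:
            xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)))
            gxp = np.zeros_like(xp)
            gw = np.zeros_like(wdta) if w.requires_grad else None
            for di in range(kh):
                for dj in range(kw):
                    xs = xp[:, :, di:di + h, dj:dj + wd]
                    if gw is not None:
                        gw[:, :, di, dj] = np.tensordot(
                            gy, xs, axes=([0, 2, 3], [0, 2, 3]))
                    gxp[:, :, di:di + h, dj:dj + wd] += np.tensordot(
                        gy, wdta[:, :, di, dj], axes=([1], [0])
                    ).transpose(0, 3, 1, 2)
            if gw is not None:
                w._accumulate(gw)
            x._accumulate(gxp[:, :, p:p + h, p:p + wd])

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda gy: x._accumulate(gy * mask)
    return out


def _window_view(a: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C, H/2, W/2, 4) with windows in row-major order."""
    n, c, h, w = a.shape
    return (a.reshape(n, c, h // 2, 2, w // 2, 2)
             .transpose(0, 1, 2, 4, 3, 5)
             .reshape(n, c, h // 2, w // 2, 4))


def _from_window_view(v: np.ndarray, h: int, w: int) -> np.ndarray:
    n, c = v.shape[:2]
    return (v.reshape(n, c, h // 2, w // 2, 2, 2)
             .transpose(0, 1, 2, 4, 3, 5)
             .reshape(n, c, h, w))


def max_pool_with_indices(x: Tensor) -> tuple[Tensor, PoolingIndices]:
    """2x2 max pooling with stride 2, recording argmax offsets."""
    x = _as_tensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max pooling requires even spatial dims, got {h}x{w}")
    v = _window_view(x.data)
    flat = v.argmax(axis=-1)  # first maximum in row-major window order
    y = np.take_along_axis(v, flat[..., None], axis=-1)[..., 0]
    idx = PoolingIndices(flat=flat, source_shape=(h, w))
    out = Tensor(y, parents=(x,))

    def backward(gy):
        gv = np.zeros_like(v)
        np.put_along_axis(gv, flat[..., None], gy[..., None], axis=-1)
        x._accumulate(_from_window_view(gv, h, w))

    out._backward = backward
    return out, idx


def max_unpool(x: Tensor, indices: PoolingIndices) -> Tensor:
    """Place each value at its recorded argmax position; zeros elsewhere."""
    x = _as_tensor(x)
    n, c, h, w = x.shape
    if (h, w) != indices.pooled_shape or indices.flat.shape[:2] != (n, c):
        raise ValueError(
            f"unpool: input {x.shape} does not match indices "
            f"{indices.flat.shape} (source {indices.source_shape})")
    hh, ww = indices.source_shape
    v = np.zeros((n, c, h, w, 4), dtype=x.data.dtype)
    np.put_along_axis(v, indices.flat[..., None], x.data[..., None], axis=-1)
    out = Tensor(_from_window_view(v, hh, ww), parents=(x,))

    def backward(gy):
        gv = _window_view(gy)
        x._accumulate(
            np.take_along_axis(gv, indices.flat[..., None], axis=-1)[..., 0])

    out._backward = backward
    return out


def upsample2(x: Tensor) -> Tensor:
    """Parameter-free nearest-neighbour x2 upsampling."""
    x = _as_tensor(x)
    n, c, h, w = x.shape
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), parents=(x,))

    def backward(gy):
        x._accumulate(gy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = backward
    return out


def concat(tensors) -> Tensor:
    """Concatenate along the channel axis."""
    tensors = [_as_tensor(t) for t in tensors]
    shapes = {t.shape[2:] for t in tensors}
    if len(shapes) != 1:
        raise ValueError(f"concat: mismatched spatial shapes {sorted(shapes)}")
    sizes = [t.shape[1] for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=1),
                 parents=tuple(tensors))
    bounds = np.cumsum([0] + sizes)

    def backward(gy):
        for t, a, b in zip(tensors, bounds[:-1], bounds[1:]):
            t._accumulate(gy[:, a:b])

    out._backward = backward
    return out


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable softmax (plain ndarray; prediction path)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


def cross_entropy(y_true: np.ndarray, y_prob: np.ndarray,
                  eps: float = 1e-12) -> float:
    """Mean per-pixel cross-entropy between a one-hot truth and a predicted
    distribution, both (N, C, H, W); log arguments are floored at ``eps``.

    Zero exactly when the prediction assigns probability 1 to the true class
    everywhere (up to the floor); use :func:`softmax_cross_entropy` for the
    numerically fused training path.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if y_true.shape != y_prob.shape:
        raise ValueError(
            f"shape mismatch: {y_true.shape} vs {y_prob.shape}")
    per_pixel = -(y_true * np.log(np.clip(y_prob, eps, None))).sum(axis=1)
    return float(per_pixel.mean())


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy between softmax(logits) and int labels.

    ``logits``: (N, C, H, W); ``labels``: (N, H, W) integers in [0, C).
    """
    logits = _as_tensor(logits)
    n, c, h, w = logits.shape
    labels = np.asarray(labels)
    if labels.shape != (n, h, w):
        raise ValueError(
            f"labels shape {labels.shape} does not match logits {logits.shape}")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    picked = np.take_along_axis(logp, labels[:, None], axis=1)[:, 0]
    loss = Tensor(-picked.mean(), parents=(logits,))

    def backward(gy):
        p = np.exp(logp)
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
        logits._accumulate(gy * (p - onehot) / (n * h * w))

    loss._backward = backward
    return loss
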