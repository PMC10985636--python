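"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package needs gradients in two places: optimizing the parameters of the
miniature segmentation/detection networks, and optimizing bounded input
perturbations against a frozen network (the adversarial-noise generator).
Both run on desk-scale 2D grids, so a small tape-based engine over numpy is
sufficient and keeps the whole pipeline dependency-light and deterministic.

Conventions
-----------
* A :class:`Tensor` wraps a float64 ``numpy`` array. Operations build a DAG;
  :meth:`Tensor.backward` runs reverse-mode accumulation in topological order.
* Image batches are ``(N, C, H, W)``; convolutions are stride-1 with "same"
  zero padding; spatial down/up-sampling is explicit (``avgpool2``,
  ``upsample2``).
* Gradients of piecewise-linear ops (relu, clip) use the standard
  zero-on-the-boundary subgradient.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "avgpool2", "upsample2"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward()

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def _bwd():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.shape))
        out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, self.requires_grad)
        out._parents = (self,)

        def _bwd():
            if self.requires_grad:
                self._accumulate(-out.grad)
        out._backward = _bwd
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def _bwd():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.shape))
        out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def _bwd():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(
                    -out.grad * self.data / other.data ** 2, other.shape))
        out._backward = _bwd
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._lift(other) / self

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, self.requires_grad)
        out._parents = (self,)

        def _bwd():
            if self.requires_grad:
                self._accumulate(out.grad * p * self.data ** (p - 1))
        out._backward = _bwd
        return out

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def _bwd():
            a, b, g = self.data, other.data, out.grad
            if self.requires_grad:
                ga = g @ np.swapaxes(b, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))
        out._backward = _bwd
        return out

    # ------------------------------------------------------------ elementwise
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad)
        out._parents = (self,)

        def _bwd():
            if self.requires_grad:
                self._accumulate(out.grad * (self.data > 0))
        out._backward = _bwd
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, self.requires_grad)
        out._parents = (self,)

        def _bwd():
            if self.requires_grad:
                self._accumulate(out.grad * s * (1.0 - s))
        out._backward = _bwd
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad)
        out._parents = (self,)

        def _bwd():
            if self.requires_grad:
                self._accumulate(out.grad * e)
        out._backward = _bwd
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad)
        out._parents = (self,)

        def _bwd():
            if self.requires_grad:
                self._accumulate(out.grad / self.data)
        out._backward = _bwd
        return out

    def clip(self, lo, hi) -> "Tensor":
        """Clamp; gradient passes only where the input is strictly inside."""
        lo = np.asarray(lo, dtype=np.float64)
        hi = np.asarray(hi, dtype=np.float64)
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad)
        out._parents = (self,)
        inside = (self.data > lo) & (self.data < hi)

        def _bwd():
            if self.requires_grad:
                self._accumulate(out.grad * inside)
        out._backward = _bwd
        return out

    # -------------------------------------------------------------- reduction
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad)
        out._parents = (self,)

        def _bwd():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    axes = (axis,) if isinstance(axis, int) else tuple(axis)
                    for ax in sorted(a % self.data.ndim for a in axes):
                        g = np.expand_dims(g, ax)
                self._accumulate(np.broadcast_to(g, self.shape).copy())
        out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad)
        out._parents = (self,)

        def _bwd():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.shape))
        out._backward = _bwd
        return out

    def transpose(self, axes: Iterable[int]) -> "Tensor":
        axes = tuple(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad)
        out._parents = (self,)
        inv = tuple(np.argsort(axes))

        def _bwd():
            if self.requires_grad:
                self._accumulate(out.grad.transpose(inv))
        out._backward = _bwd
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors))
    out._parents = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bwd():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(out.grad[tuple(sl)])
    out._backward = _bwd
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1 same-padding 2D convolution (cross-correlation).

    ``x``: (N, C, H, W); ``w``: (F, C, k, k); ``b``: (F,). Implemented as a
    sum of k*k shifted channel-contraction matmuls in channels-last layout,
    which avoids materializing im2col buffers.
    """
    n, c, h, wd = x.shape
    f, c2, k, k2 = w.shape
    if c != c2 or k != k2:
        raise ValueError(f"conv2d shape mismatch: x{x.shape} w{w.shape}")
    p = k // 2
    # channels-last padded copy: (N, H+2p, W+2p, C)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))
                ).transpose(0, 2, 3, 1).copy()
    y = np.zeros((n, h, wd, f))
    for i in range(k):
        for j in range(k):
            y += xp[:, i:i + h, j:j + wd, :] @ w.data[:, :, i, j].T
    if b is not None:
        y += b.data
    out = Tensor(y.transpose(0, 3, 1, 2),
                 x.requires_grad or w.requires_grad
                 or (b is not None and b.requires_grad))
    out._parents = (x, w) if b is None else (x, w, b)

    def _bwd():
        g = out.grad.transpose(0, 2, 3, 1).copy()               # (N, H, W, F)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        need_x = x.requires_grad
        gxp = np.zeros((n, h + 2 * p, wd + 2 * p, c)) if need_x else None
        if w.requires_grad:
            gw = np.empty((f, c, k, k))
            gflat = g.reshape(-1, f)
        for i in range(k):
            for j in range(k):
                if w.requires_grad:
                    patch = xp[:, i:i + h, j:j + wd, :].reshape(-1, c)
                    gw[:, :, i, j] = gflat.T @ patch
                if need_x:
                    gxp[:, i:i + h, j:j + wd, :] += g @ w.data[:, :, i, j]
        if w.requires_grad:
            w._accumulate(gw)
        if need_x:
            x._accumulate(
                gxp[:, p:p + h, p:p + wd, :].transpose(0, 3, 1, 2))
    out._backward = _bwd
    return out


def avgpool2(x: Tensor) -> Tensor:
    """2x2 average pooling; spatial dims must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("avgpool2 requires even spatial dims")
    y = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
    out = Tensor(y, x.requires_grad)
    out._parents = (x,)

    def _bwd():
        if x.requires_grad:
            g = np.repeat(np.repeat(out.grad, 2, axis=2), 2, axis=3) * 0.25
            x._accumulate(g)
    out._backward = _bwd
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    y = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor(y, x.requires_grad)
    out._parents = (x,)
    n, c, h, w = x.shape

    def _bwd():
        if x.requires_grad:
            g = out.grad.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
            x._accumulate(g)
    out._backward = _bwd
    return out
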