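"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the pair-track network in this package: broadcast
-aware elementwise ops, (batched) matmul, reductions, reshapes/transposes,
slicing and constant padding, a numerically stable softmax, sigmoid/tanh,
and binary cross-entropy with logits.  Gradients accumulate into ``.grad``
after calling :meth:`Tensor.backward` on a scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "softmax", "bce_with_logits", "clip_ste"]


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reverse numpy broadcasting: reduce grad down to `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    # -- elementwise ----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_sum_to_shape(g, self.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_sum_to_shape(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        def backward(g, out):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        return self._make(self.data**exponent, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g, out):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def tanh(self):
        t = np.tanh(self.data)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * (1.0 - t * t))

        return self._make(t, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * sign)

        return self._make(np.abs(self.data), (self,), backward)

    # -- linear algebra ---------------------------------------------------
    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, out):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_sum_to_shape(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_sum_to_shape(gb, other.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, out):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.shape

        def backward(g, out):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, out):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(self.data[idx], (self,), backward)

    def pad(self, pad_width):
        """Constant (zero) padding; pad_width as for np.pad."""
        slices = tuple(
            slice(p[0], p[0] + n) for p, n in zip(pad_width, self.shape, strict=True)
        )

        def backward(g, out):
            if self.requires_grad:
                self._accum(g[slices])

        return self._make(np.pad(self.data, pad_width), (self,), backward)

    # -- autograd engine ----------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited = set()

        def visit(t: Tensor):
            if id(t) in visited or not t.requires_grad:
                return
            visited.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad, t)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g, out):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accum(y * (g - dot))

    return x._make(y, (x,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray, weights: np.ndarray | None = None) -> Tensor:
    """Numerically stable elementwise binary cross entropy, mean-reduced,
    with optional per-element weights (weighted mean)."""
    z = logits.data
    t = np.asarray(targets, dtype=np.float64)
    w = np.ones_like(z) if weights is None else np.asarray(weights, dtype=np.float64)
    loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    wsum = w.sum()
    value = (loss * w).sum() / wsum

    def backward(g, out):
        if logits.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-z))
            logits._accum(g * w * (sig - t) / wsum)

    return logits._make(np.asarray(value), (logits,), backward)


def clip_ste(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip values with a straight-through (identity) gradient, so values
    pushed outside the range can still be pulled back during training."""

    def backward(g, out):
        if x.requires_grad:
            x._accum(g)

    return x._make(np.clip(x.data, lo, hi), (x,), backward)
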