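"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps an ndarray,
records the operations that produced it, and :meth:`Tensor.backward` runs the
chain rule over the recorded graph in reverse topological order.  The op set
is exactly what the encoder-decoder network and its losses need — elementwise
arithmetic with broadcasting, matmul (batched), exp/log/relu/sigmoid, axis
reductions, reshapes/transposes, slicing, padding, and concatenation.

Everything is float64 and single-threaded numpy; correctness of every
backward rule is pinned by finite-difference gradient checks in the test
suite.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self.grad = None
        self._prev = _prev if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- introspection ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd -----------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may alias an upstream buffer
            self.grad = np.array(g, dtype=float)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self) -> None:
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, power(other, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return tsum(self, axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, axes):
        return transpose(self, axes)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# primitive ops

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, _prev=(a, b))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = _bw
    return out


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, _prev=(a, b))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = _bw
    return out


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data @ b.data, _prev=(a, b))

    def _bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    out._backward = _bw
    return out


def power(a, p: float) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data ** p, _prev=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1.0))

    out._backward = _bw
    return out


def exp(a) -> Tensor:
    a = _wrap(a)
    out = Tensor(np.exp(a.data), _prev=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g * out.data)

    out._backward = _bw
    return out


def log(a) -> Tensor:
    a = _wrap(a)
    out = Tensor(np.log(a.data), _prev=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    out._backward = _bw
    return out


def relu(a) -> Tensor:
    a = _wrap(a)
    out = Tensor(np.maximum(a.data, 0.0), _prev=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g * (a.data > 0))

    out._backward = _bw
    return out


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    y = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(y, _prev=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g * y * (1.0 - y))

    out._backward = _bw
    return out


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), _prev=(a,))

    def _bw(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(a_ % a.data.ndim for a_ in axes):
                g = np.expand_dims(g, ax)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    out._backward = _bw
    return out


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data.reshape(shape), _prev=(a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    out._backward = _bw
    return out


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data.transpose(axes), _prev=(a,))
    inv = np.argsort(axes)

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    out._backward = _bw
    return out


def tslice(a, index) -> Tensor:
    """Slice with basic (slice/int-free) indexing; backward scatters."""
    a = _wrap(a)
    out = Tensor(a.data[index], _prev=(a,))

    def _bw(g):
        if a.requires_grad:
            if a.grad is None:
                a.grad = np.zeros_like(a.data)
            a.grad[index] += g

    out._backward = _bw
    return out


def pad(a, pad_width) -> Tensor:
    """Zero-pad; `pad_width` as for np.pad."""
    a = _wrap(a)
    out = Tensor(np.pad(a.data, pad_width), _prev=(a,))
    slices = tuple(slice(lo, lo + s) for (lo, _), s in zip(pad_width, a.data.shape))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g[slices])

    out._backward = _bw
    return out


def concat(tensors: Sequence, axis: int = -1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# composites

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x.data.max(axis=axis, keepdims=True)
    e = exp(x - Tensor(shift))
    return e / tsum(e, axis=axis, keepdims=True)


def softplus(x: Tensor) -> Tensor:
    """log(1 + e^x), computed stably as relu(x) + log1p(e^-|x|)."""
    ax = relu(x) + relu(-x)  # |x|
    return relu(x) + log(exp(-ax) + 1.0)


def bce_with_logits(z: Tensor, target: np.ndarray, pos_weight: float = 1.0) -> Tensor:
    """Elementwise binary cross-entropy on logits.

    ``pos_weight`` scales the positive-class term, the usual remedy for the
    heavy unpaired/paired imbalance of contact matrices.
    """
    # w*y*softplus(-z) + (1-y)*softplus(z) = (1-y+w*y)*softplus(z) - w*y*z
    y = np.asarray(target, dtype=float)
    return softplus(z) * Tensor(1.0 - y + pos_weight * y) - z * Tensor(pos_weight * y)


def masked_mean(x: Tensor, mask: np.ndarray) -> Tensor:
    m = np.asarray(mask, dtype=float)
    denom = float(m.sum())
    if denom == 0:
        return Tensor(0.0)
    return tsum(x * Tensor(m)) * (1.0 / denom)


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
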