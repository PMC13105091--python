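"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to express and train the desk-scale multi-modal
transformer: broadcasting arithmetic, batched matmul, reductions, softmax,
embedding lookup, concatenation and slicing.  Gradients are accumulated by
topological traversal of the recorded graph.  Primitive gradients are
verified against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "embedding", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._prev: tuple["Tensor", ...] = ()

    # -- graph bookkeeping --------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._prev for p in parents):
            out.requires_grad = any(p.requires_grad for p in parents)
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward():
            self_grad = _unbroadcast(out.grad, self.data.shape)
            other_grad = _unbroadcast(out.grad, other.data.shape)
            self._accum(self_grad)
            other._accum(other_grad)

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward():
            self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return (-self) + other

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other.power(-1.0)

    def power(self, p: float) -> "Tensor":
        out_data = np.power(self.data, p)

        def backward():
            self._accum(out.grad * p * np.power(self.data, p - 1.0))

        out = self._make(out_data, (self,), backward)
        return out

    def sqrt(self) -> "Tensor":
        return self.power(0.5)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = np.matmul(self.data, other.data)

        def backward():
            a, b, g = self.data, other.data, out.grad
            if a.ndim == 1 and b.ndim == 1:
                self._accum(g * b)
                other._accum(g * a)
                return
            a2 = a[None, :] if a.ndim == 1 else a
            b2 = b[:, None] if b.ndim == 1 else b
            g2 = np.reshape(g, np.matmul(a2, b2).shape)
            ga = np.matmul(g2, np.swapaxes(b2, -1, -2))
            gb = np.matmul(np.swapaxes(a2, -1, -2), g2)
            self._accum(_unbroadcast(ga, a2.shape).reshape(a.shape))
            other._accum(_unbroadcast(gb, b2.shape).reshape(b.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    # -- shaping -------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        out_data = self.data.reshape(*shape)

        def backward():
            self._accum(out.grad.reshape(self.data.shape))

        out = self._make(out_data, (self,), backward)
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out_data = np.swapaxes(self.data, a, b)

        def backward():
            self._accum(np.swapaxes(out.grad, a, b))

        out = self._make(out_data, (self,), backward)
        return out

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        out_data = np.transpose(self.data, axes)
        inv = np.argsort(axes)

        def backward():
            self._accum(np.transpose(out.grad, inv))

        out = self._make(out_data, (self,), backward)
        return out

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def backward():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)

        out = self._make(out_data, (self,), backward)
        return out

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            g = out.grad
            if not keepdims and axis is not None:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities -------------------------------------------------------

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)

        def backward():
            self._accum(out.grad * (self.data > 0))

        out = self._make(out_data, (self,), backward)
        return out

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward():
            self._accum(out.grad * (1.0 - out_data**2))

        out = self._make(out_data, (self,), backward)
        return out

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward():
            self._accum(out.grad * out_data * (1.0 - out_data))

        out = self._make(out_data, (self,), backward)
        return out

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward():
            self._accum(out.grad * out_data)

        out = self._make(out_data, (self,), backward)
        return out

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward():
            self._accum(out.grad / self.data)

        out = self._make(out_data, (self,), backward)
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward():
            g = out.grad
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))

        out = self._make(s, (self,), backward)
        return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out_data.ndim
            sl[axis] = slice(lo, hi)
            t._accum(out.grad[tuple(sl)])

    out = tensors[0]._make(out_data, tuple(tensors), backward)
    return out


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup ``weight[idx]`` with scatter-add gradient."""
    idx = np.asarray(idx, dtype=np.intp)
    out_data = weight.data[idx]

    def backward():
        g = np.zeros_like(weight.data)
        np.add.at(g, idx, out.grad)
        weight._accum(g)

    out = weight._make(out_data, (weight,), backward)
    return out


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = [p for p in params if p.requires_grad]
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
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
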