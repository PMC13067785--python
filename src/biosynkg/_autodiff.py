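"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the embedding model needs: dense matmul,
broadcast add/sub/mul, elementwise tanh/relu/exp/log/sqrt/square, row
gather, axis sums and concatenation.  Gradients of broadcast operations
are un-broadcast by summing over the expanded axes.  An Adam optimizer is
included.  Everything is float64 and seeded explicitly by the caller.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # keep numpy from hijacking binary ops

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing --------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        def backward(g):
            self._accum(g)
            other._accum(g)
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        def backward(g):
            self._accum(g * other.data)
            other._accum(g * self.data)
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        def backward(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)
        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)
        def backward(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)
        return self._make(self.data @ other.data, (self, other), backward)

    # -- elementwise -----------------------------------------------------
    def square(self):
        def backward(g):
            self._accum(2.0 * g * self.data)
        return self._make(self.data**2, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)
        def backward(g):
            self._accum(g / (2.0 * np.maximum(out_data, 1e-30)))
        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)
        def backward(g):
            self._accum(g * out_data)
        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)
        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)
        def backward(g):
            self._accum(g * (1.0 - out_data**2))
        return self._make(out_data, (self,), backward)

    def relu(self):
        def backward(g):
            self._accum(g * (self.data > 0))
        return self._make(np.maximum(self.data, 0.0), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))
        return self._make(out_data, (self,), backward)

    # -- shape / reduce --------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def gather_rows(self, idx) -> "Tensor":
        """Select rows by (possibly repeated, possibly 2-D) integer index."""
        idx = np.asarray(idx)
        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, idx.ravel(), g.reshape(-1, self.data.shape[-1]))
            self._accum(grad)
        return self._make(self.data[idx], (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape
        def backward(g):
            self._accum(g.reshape(old))
        return self._make(self.data.reshape(*shape), (self,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
    )
    if out.requires_grad:
        def backward(g):
            start = 0
            for t, s in zip(tensors, sizes):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + s)
                t._accum(g[tuple(sl)])
                start += s
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def logsumexp(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable log-sum-exp along ``axis``.

    ``mask`` (0/1 array broadcastable to x) restricts the sum to masked-in
    entries; the max is detached (a constant shift), which is exact.
    """
    m = x.data if mask is None else np.where(mask > 0, x.data, -np.inf)
    shift = np.max(m, axis=axis, keepdims=True)
    shift = np.where(np.isfinite(shift), shift, 0.0)  # constant, detached
    z = (x - Tensor(shift)).exp()
    if mask is not None:
        z = z * Tensor(mask)
    return z.sum(axis=axis).log() + Tensor(np.squeeze(shift, axis=axis))


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)
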