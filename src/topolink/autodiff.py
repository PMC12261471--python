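"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the models in this package: dense layers, ReLU and
sigmoid gates, batch normalization, dropout, mean aggregation (a matmul with
a fixed row-normalized adjacency) and the logistic loss.  Tensors wrap
float64 arrays; gradients are accumulated by a topological-order backward
pass.  Gradient correctness is checked against finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad over axes that were broadcast to reach `shape`'s gradient."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g, b.data.shape)

        return self._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += _unbroadcast(-g, a.data.shape)

        return self._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g * b.data, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g * a.data, b.data.shape)

        return self._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g / b.data, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(-g * a.data / b.data**2, b.data.shape)

        return self._from_op(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += g @ b.data.T
            if b.requires_grad:
                b.grad += a.data.T @ g

        return self._from_op(self.data @ other.data, (self, other), backward)

    def __pow__(self, p: float):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += g * p * a.data ** (p - 1)

        return self._from_op(self.data**p, (self,), backward)

    # -- nonlinearities -------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a.grad += g * m

        return self._from_op(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = np.where(self.data >= 0,
                     1.0 / (1.0 + np.exp(-np.abs(self.data))),
                     np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))))

        def backward(g, a=self, s=s):
            if a.requires_grad:
                a.grad += g * s * (1.0 - s)

        return self._from_op(s, (self,), backward)

    def softplus(self):
        """log(1 + exp(x)), numerically stable; gradient is sigmoid(x)."""
        out = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = np.where(self.data >= 0,
                       1.0 / (1.0 + np.exp(-np.abs(self.data))),
                       np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))))

        def backward(g, a=self, s=sig):
            if a.requires_grad:
                a.grad += g * s

        return self._from_op(out, (self,), backward)

    # -- reductions and shaping -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self):
            if a.requires_grad:
                gg = np.asarray(g)
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                a.grad += np.broadcast_to(gg, a.data.shape)

        return self._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def take_rows(self, idx: np.ndarray):
        idx = np.asarray(idx, dtype=np.intp)

        def backward(g, a=self, idx=idx):
            if a.requires_grad:
                np.add.at(a.grad, idx, g)

        return self._from_op(self.data[idx], (self,), backward)

    def reshape(self, *shape):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += g.reshape(a.data.shape)

        return self._from_op(self.data.reshape(*shape), (self,), backward)

    # -- autodiff driver -------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if p.requires_grad and id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, offs=offsets):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]

    return Tensor._from_op(np.concatenate([t.data for t in tensors], axis=axis),
                           tuple(tensors), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = np.zeros_like(p.data)

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
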