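"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The training objectives in this package (multi-view NT-Xent, CCA
invariance/decorrelation) and their encoders (a three-layer fusion MLP, a
two-layer GCN) are small enough that a dependency-free, CPU-deterministic
engine is the right tool: every op used by the models is defined here with
its vector-Jacobian product, and the test suite checks gradients of the
composite losses against central finite differences.

Usage mirrors the familiar define-by-run style::

    w = Tensor(np.zeros((3, 2)), requires_grad=True)
    loss = ((x @ w).relu() ** 2).sum()
    loss.backward()
    w.grad  # ndarray

Only what the models need is implemented: matmul, transpose, elementwise
arithmetic with broadcasting, relu, exp/log/sqrt, power, sum/mean along
axes, and clip_min.  Gradients for broadcast operands are summed back to the
operand's shape.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Adam", "relu", "l2_normalize_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)

        def bw(g, a=self, b=other, out_shapes=(self.shape, other.shape)):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data**2), b.shape))

        return self._make(self.data / other.data, (self, other), bw)

    def __pow__(self, p: float):
        def bw(g, a=self, p=p):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return self._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = Tensor._lift(other)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    # -- shape / reductions --------------------------------------------------
    @property
    def T(self) -> "Tensor":
        def bw(g, a=self):
            if a.requires_grad:
                a._accum(g.T)

        return self._make(self.data.T, (self,), bw)

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g, a=self, mask=mask):
            if a.requires_grad:
                a._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g, a=self, od=out_data):
            if a.requires_grad:
                a._accum(g * od)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return self._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g, a=self, od=out_data):
            if a.requires_grad:
                a._accum(g / (2.0 * od))

        return self._make(out_data, (self,), bw)

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes through where x > lo."""
        mask = self.data > lo

        def bw(g, a=self, mask=mask):
            if a.requires_grad:
                a._accum(g * mask)

        return self._make(np.maximum(self.data, lo), (self,), bw)

    # -- backward ------------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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


def relu(x: Tensor) -> Tensor:
    return x.relu()


def l2_normalize_rows(z: Tensor, eps: float = 1e-12) -> Tensor:
    """Divide each row by its L2 norm (floored at ``eps``)."""
    sq = (z * z).sum(axis=1, keepdims=True)
    return z / sq.clip_min(eps * eps).sqrt()


class Adam:
    """Adam optimizer over a list of parameter Tensors (deterministic)."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))
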