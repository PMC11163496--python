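"""Reverse-mode autodiff on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operation that
produced it; :meth:`Tensor.backward` walks the graph in reverse topological
order accumulating gradients.  Only the operations the hybrid classifier
needs are implemented; each op defines its exact vector-Jacobian product.
All arithmetic supports NumPy broadcasting (gradients are summed back to
the operand shape).
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

#: float dtype for all tensors; float32 for speed, switchable to float64
#: (e.g. in gradient-verification tests)
DTYPE = np.float32

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


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
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(DTYPE, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
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
        self._accum(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        a = self

        def bw(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __pow__(self, p: float) -> "Tensor":
        a = self

        def bw(g):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(a.data ** p, (a,), bw)

    def matmul(self, other: "Tensor") -> "Tensor":
        """Batched matrix multiply; leading dims of both operands must match."""
        a, b = self, self._wrap(other)

        def bw(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), bw)

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        a = self
        old = a.data.shape

        def bw(g):
            a._accum(g.reshape(old))

        return Tensor._make(a.data.reshape(*shape), (a,), bw)

    def transpose(self, *axes) -> "Tensor":
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accum(np.transpose(g, inv))

        return Tensor._make(np.transpose(a.data, axes), (a,), bw)

    def roll(self, shifts: tuple[int, ...], axes: tuple[int, ...]) -> "Tensor":
        a = self

        def bw(g):
            a._accum(np.roll(g, tuple(-s for s in shifts), axes))

        return Tensor._make(np.roll(a.data, shifts, axes), (a,), bw)

    def __getitem__(self, idx) -> "Tensor":
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._make(a.data[idx], (a,), bw)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).astype(DTYPE))
                return
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.data.shape).astype(DTYPE))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def bw(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bw)

    def sigmoid(self) -> "Tensor":
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accum(g * s * (1.0 - s))

        return Tensor._make(s, (a,), bw)

    def gelu(self) -> "Tensor":
        """Exact (erf-based) Gaussian error linear unit."""
        a = self
        x = a.data
        cdf = 0.5 * (1.0 + erf(x / _SQRT2))

        def bw(g):
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
            a._accum(g * (cdf + x * pdf))

        return Tensor._make(x * cdf, (a,), bw)

    def exp(self) -> "Tensor":
        a = self
        e = np.exp(a.data)

        def bw(g):
            a._accum(g * e)

        return Tensor._make(e, (a,), bw)

    def log(self) -> "Tensor":
        a = self

        def bw(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bw)

    def sqrt(self) -> "Tensor":
        a = self
        r = np.sqrt(a.data)

        def bw(g):
            a._accum(g * 0.5 / r)

        return Tensor._make(r, (a,), bw)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self + Tensor(-self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under ``logits`` rows."""
    n = logits.shape[0]
    shifted = logits + Tensor(-logits.data.max(axis=1, keepdims=True))
    lse = shifted.exp().sum(axis=1, keepdims=True).log()
    logp = shifted - lse
    picked = logp[np.arange(n), np.asarray(labels)]
    return -picked.mean()
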