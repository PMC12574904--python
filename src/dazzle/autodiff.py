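"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core the network-inference model trains on. It supports
exactly the operations the model needs — elementwise arithmetic and
activations, dense matrix products, a gene-axis mixing product against an
``m x m`` matrix and its inverse (via linear solve, never explicit
inversion), and scalar reductions — with float64 throughout so that seeded
runs are bitwise reproducible on CPU.

Gradients follow the usual vector-Jacobian rules; broadcasting in ``+`` and
``*`` is undone by summing the upstream gradient over the broadcast axes.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Adam", "tanh", "sigmoid", "gene_mix", "gene_unmix"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def size(self) -> int:
        return self.data.size

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # own a fresh buffer: upstream may hand us a view of its own grad
            self.grad = np.array(grad, dtype=np.float64, copy=True)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(grad, self.data.shape).copy()
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("division only supported by python scalars")
        return self * (1.0 / float(scalar))

    def matmul(self, other: "Tensor") -> "Tensor":
        """``self @ other`` where other is 2-D; self may have leading axes."""
        other = self._wrap(other)
        data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                a = self.data.reshape(-1, self.data.shape[-1])
                gg = g.reshape(-1, g.shape[-1])
                other._accum(a.T @ gg)

        return self._make(data, (self, other), backward)

    __matmul__ = matmul

    # -- activations / elementwise -------------------------------------------
    def tanh(self) -> "Tensor":
        data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - data * data))

        return self._make(data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        # clipped input keeps exp() finite; logistic saturates well before +-500
        data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * data * (1.0 - data))

        return self._make(data, (self,), backward)

    def exp(self) -> "Tensor":
        data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * data)

        return self._make(data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def square(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(g * 2.0 * self.data)

        return self._make(self.data ** 2, (self,), backward)

    def abs(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))

        return self._make(np.abs(self.data), (self,), backward)

    def clamp(self, lo: float, hi: float) -> "Tensor":
        """Clip values; gradient passes through only inside the bounds."""
        data = np.clip(self.data, lo, hi)
        inside = (self.data > lo) & (self.data < hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * inside)

        return self._make(data, (self,), backward)

    def reshape(self, *shape: int) -> "Tensor":
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(np.asarray(self.data.sum()), (self,), backward)

    def mean(self) -> "Tensor":
        return self.sum() / self.data.size

    # -- autodiff driver ------------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from a scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def tanh(t: Tensor) -> Tensor:
    return t.tanh()


def sigmoid(t: Tensor) -> Tensor:
    return t.sigmoid()


def gene_mix(h: Tensor, m: Tensor) -> Tensor:
    """Right-multiply along the gene axis: ``out[:, k, c] = sum_j h[:, j, c] m[j, k]``.

    `h` has shape (cells, genes, channels); `m` is (genes, genes).
    """
    data = np.einsum("njc,jk->nkc", h.data, m.data)

    def backward(g):
        if h.requires_grad:
            h._accum(np.einsum("nkc,jk->njc", g, m.data))
        if m.requires_grad:
            m._accum(np.einsum("njc,nkc->jk", h.data, g))

    return h._make(data, (h, m), backward)


def gene_unmix(s: Tensor, m: Tensor) -> Tensor:
    """Solve ``out @ m = s`` along the gene axis, i.e. ``out = s m^{-1}``.

    Implemented as a linear solve against ``m.T``; raises
    ``numpy.linalg.LinAlgError`` when ``m`` is singular. The gradient w.r.t.
    ``m`` is ``-out^T g m^{-T}`` summed over channels.
    """
    n, mg, c = s.data.shape
    # solve m.T @ x.T = s.T per channel: stack channels into columns
    rhs = s.data.transpose(1, 0, 2).reshape(mg, n * c)
    sol = np.linalg.solve(m.data.T, rhs)
    data = sol.reshape(mg, n, c).transpose(1, 0, 2)

    def backward(g):
        grhs = g.transpose(1, 0, 2).reshape(mg, n * c)
        gsol = np.linalg.solve(m.data, grhs)  # = m^{-T} applied from the left
        g_s = gsol.reshape(mg, n, c).transpose(1, 0, 2)
        if s.requires_grad:
            s._accum(g_s)
        if m.requires_grad:
            m._accum(-np.einsum("njc,nkc->jk", data, g_s))

    return s._make(data, (s, m), backward)


class Adam:
    """Adam with parameter groups carrying their own learning rates."""

    def __init__(self, groups: Iterable[dict], betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.groups = [dict(g) for g in groups]
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        for g in self.groups:
            for p in g["params"]:
                self._m[id(p)] = np.zeros_like(p.data)
                self._v[id(p)] = np.zeros_like(p.data)

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for g in self.groups:
            lr = g["lr"]
            for p in g["params"]:
                if p.grad is None:
                    continue
                m = self._m[id(p)]
                v = self._v[id(p)]
                m *= self.b1
                m += (1.0 - self.b1) * p.grad
                v *= self.b2
                v += (1.0 - self.b2) * p.grad ** 2
                p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
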