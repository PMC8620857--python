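"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the message-passing network: dense matmul,
broadcast-aware elementwise arithmetic, the usual activations, row
gather/scatter for graph message passing, row concatenation, softmax, and
reductions.  Gradients are accumulated by a topological backward sweep over
the recorded tape.  Correctness is pinned down by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat_rows",
    "gather_rows",
    "scatter_add_rows",
    "softmax",
    "relu",
    "sigmoid",
    "tanh",
    "repeat_cols",
    "sum_col_groups",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    @property
    def T(self):
        def backward(g, a=self):
            a._accum(g.T)

        return self._make(self.data.T, (self,), backward)

    def sum(self):
        def backward(g, a=self):
            a._accum(np.full_like(a.data, float(g)))

        return self._make(self.data.sum(), (self,), backward)

    def reshape(self, *shape):
        def backward(g, a=self):
            a._accum(g.reshape(a.data.shape))

        return self._make(self.data.reshape(*shape), (self,), backward)

    # -- backward machinery ---------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# -- activations and structured ops -------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g, a=x, m=mask):
        a._accum(g * m)

    return Tensor._make(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g, a=x, s=s):
        a._accum(g * s * (1.0 - s))

    return Tensor._make(s, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)

    def backward(g, a=x, t=t):
        a._accum(g * (1.0 - t * t))

    return Tensor._make(t, (x,), backward)


def softmax(x: Tensor) -> Tensor:
    """Softmax over all entries of ``x`` (used per-graph over node scores)."""
    z = x.data - x.data.max()
    e = np.exp(z)
    s = e / e.sum()

    def backward(g, a=x, s=s):
        a._accum(s * (g - (g * s).sum()))

    return Tensor._make(s, (x,), backward)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g, a=x, idx=idx):
        out = np.zeros_like(a.data)
        np.add.at(out, idx, g)
        a._accum(out)

    return Tensor._make(x.data[idx], (x,), backward)


def scatter_add_rows(x: Tensor, idx: np.ndarray, n_rows: int) -> Tensor:
    """Rows of ``x`` summed into a zero (n_rows, d) array at positions ``idx``."""
    idx = np.asarray(idx, dtype=np.intp)
    out = np.zeros((n_rows, x.data.shape[1]), dtype=np.float64)
    np.add.at(out, idx, x.data)

    def backward(g, a=x, idx=idx):
        a._accum(g[idx])

    return Tensor._make(out, (x,), backward)


def repeat_cols(x: Tensor, k: int) -> Tensor:
    """(n, m) -> (n, m*k): column j becomes columns j*k .. j*k+k-1."""

    def backward(g, a=x, k=k):
        n, m = a.data.shape
        a._accum(g.reshape(n, m, k).sum(axis=2))

    return Tensor._make(np.repeat(x.data, k, axis=1), (x,), backward)


def sum_col_groups(x: Tensor, n_groups: int) -> Tensor:
    """(n, n_groups*m) -> (n, m), summing column blocks of size m."""
    n, total = x.data.shape
    m = total // n_groups

    def backward(g, a=x, n_groups=n_groups):
        a._accum(np.tile(g, (1, n_groups)))

    return Tensor._make(x.data.reshape(n, n_groups, m).sum(axis=1), (x,), backward)


def concat_rows(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum([t.data.shape[axis] for t in tensors])[:-1]

    def backward(g, ts=tensors, splits=splits, axis=axis):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(data, tuple(tensors), backward)
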