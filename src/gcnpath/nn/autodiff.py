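"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the pathway/atom graph encoders need:
broadcast arithmetic, (batched) matrix products, ELU/ReLU/LeakyReLU, exp,
concatenation, row gather/scatter, per-segment sums and maxima, and
reductions.  Gradients accumulate into ``Tensor.grad`` during ``backward``;
intermediate tensors keep their gradients, which is what Grad-CAM reads.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "scatter_sum", "segment_max", "matmul_const_left"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # ---- graph machinery -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed needs a scalar output")
            grad = np.ones_like(self.data)
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        """2D @ 2D, or batched 3D @ 2D (last axis contracted)."""
        other = self._lift(other)
        a, b = self.data, other.data
        if a.ndim == 2 and b.ndim == 2:
            out = Tensor(a @ b, parents=(self, other))

            def bwd(g):
                if self.requires_grad:
                    self._accumulate(g @ b.T)
                if other.requires_grad:
                    other._accumulate(a.T @ g)

        elif a.ndim == 3 and b.ndim == 2:
            out = Tensor(np.einsum("bpf,fg->bpg", a, b), parents=(self, other))

            def bwd(g):
                if self.requires_grad:
                    self._accumulate(np.einsum("bpg,gf->bpf", g, b.T))
                if other.requires_grad:
                    other._accumulate(np.einsum("bpf,bpg->fg", a, g))

        else:
            raise ValueError(f"unsupported matmul shapes {a.shape} @ {b.shape}")
        out._backward = bwd
        return out

    # ---- nonlinearities --------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * mask)
        return out

    def elu(self, alpha: float = 1.0):
        neg = self.data <= 0
        exp_term = np.exp(np.minimum(self.data, 0.0))
        val = np.where(neg, alpha * (exp_term - 1.0), self.data)
        out = Tensor(val, parents=(self,))
        deriv = np.where(neg, alpha * exp_term, 1.0)
        out._backward = lambda g: self.requires_grad and self._accumulate(g * deriv)
        return out

    def leaky_relu(self, slope: float = 0.2):
        deriv = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * deriv, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * deriv)
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * val)
        return out

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g.reshape(orig))
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0, *sizes])

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``x[idx]`` (first axis)."""
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(x.data[idx], parents=(x,))

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, idx, g)
            x._accumulate(gx)

    out._backward = bwd
    return out


def scatter_sum(x: Tensor, idx: np.ndarray, n: int) -> Tensor:
    """Sum rows of ``x`` into ``n`` output rows keyed by ``idx``."""
    idx = np.asarray(idx, dtype=np.int64)
    val = np.zeros((n, *x.data.shape[1:]), dtype=np.float64)
    np.add.at(val, idx, x.data)
    out = Tensor(val, parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(g[idx])
    return out


def segment_max(x: Tensor, idx: np.ndarray, n: int) -> Tensor:
    """Per-segment columnwise maximum (global max pooling over graphs).

    The gradient flows to the first attaining row per (segment, column),
    matching the usual max-pool convention.
    """
    idx = np.asarray(idx, dtype=np.int64)
    n_cols = x.data.shape[1]
    val = np.full((n, n_cols), -np.inf)
    argmax = np.zeros((n, n_cols), dtype=np.int64)
    for seg in range(n):
        rows = np.flatnonzero(idx == seg)
        if rows.size == 0:
            val[seg] = 0.0
            argmax[seg] = -1
            continue
        sub = x.data[rows]
        best = sub.argmax(axis=0)
        val[seg] = sub[best, np.arange(n_cols)]
        argmax[seg] = rows[best]
    out = Tensor(val, parents=(x,))

    def bwd(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        for seg in range(n):
            if argmax[seg, 0] < 0:
                continue
            np.add.at(gx, (argmax[seg], np.arange(n_cols)), g[seg])
        x._accumulate(gx)

    out._backward = bwd
    return out


def matmul_const_left(a: np.ndarray, x: Tensor) -> Tensor:
    """``a @ x`` with a constant (non-differentiated) left matrix.

    ``a`` is (P, P); ``x`` is (B, P, F) or (P, F).  Used for the normalized
    adjacency products in graph convolutions.
    """
    if x.data.ndim == 3:
        out = Tensor(np.einsum("pq,bqf->bpf", a, x.data), parents=(x,))
        out._backward = lambda g: x.requires_grad and x._accumulate(
            np.einsum("qp,bpf->bqf", a.T.copy(), g)
        )
    else:
        out = Tensor(a @ x.data, parents=(x,))
        out._backward = lambda g: x.requires_grad and x._accumulate(a.T @ g)
    return out
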