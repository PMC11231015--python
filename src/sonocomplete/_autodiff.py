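"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the completion network needs: broadcasted
arithmetic, matmul, relu/tanh/exp/log, axis reductions (sum/mean/max),
reshape/concat, index gathering, softmax, a clamp, and a Chamfer-distance
node whose nearest-neighbor correspondence is treated as locally constant
(the standard treatment: the argmin is piecewise constant in the points).

Values are float64 throughout; graphs are built eagerly and freed after
``backward``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph plumbing -----------------------------------------------------

    @property
    def shape(self):
        return self.value.shape

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.value)
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            node._backward = None  # free closures

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out_val = self.value + other.value

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.value.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.value.shape))

        return Tensor(out_val, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor(-self.value, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_val = self.value * other.value

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.value, self.value.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.value, other.value.shape))

        return Tensor(out_val, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        out_val = self.value**exponent

        def bw(g):
            self._accumulate(g * exponent * self.value ** (exponent - 1))

        return Tensor(out_val, parents=(self,), backward=bw)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out_val = self.value @ other.value

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(other.value, -1, -2), self.value.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(self.value, -1, -2) @ g, other.value.shape))

        return Tensor(out_val, parents=(self, other), backward=bw)

    __matmul__ = matmul

    # -- nonlinearities -----------------------------------------------------

    def relu(self):
        mask = self.value > 0

        def bw(g):
            self._accumulate(g * mask)

        return Tensor(self.value * mask, parents=(self,), backward=bw)

    def tanh(self):
        out_val = np.tanh(self.value)

        def bw(g):
            self._accumulate(g * (1 - out_val**2))

        return Tensor(out_val, parents=(self,), backward=bw)

    def exp(self):
        out_val = np.exp(self.value)

        def bw(g):
            self._accumulate(g * out_val)

        return Tensor(out_val, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.value)

        return Tensor(np.log(self.value), parents=(self,), backward=bw)

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient passes only inside the interval."""
        mask = (self.value >= lo) & (self.value <= hi)

        def bw(g):
            self._accumulate(g * mask)

        return Tensor(np.clip(self.value, lo, hi), parents=(self,), backward=bw)

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        orig = self.value.shape

        def bw(g):
            self._accumulate(g.reshape(orig))

        return Tensor(self.value.reshape(*shape), parents=(self,), backward=bw)

    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.value.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.value.shape).copy())

        return Tensor(self.value.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max over one axis; gradient routes to (first) argmax entries."""
        idx = np.argmax(self.value, axis=axis)
        out_val = np.take_along_axis(self.value, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out_val = np.squeeze(out_val, axis=axis)

        def bw(g):
            full = np.zeros_like(self.value)
            g_exp = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(full, np.expand_dims(idx, axis), g_exp, axis=axis)
            self._accumulate(full)

        return Tensor(out_val, parents=(self,), backward=bw)

    def softmax(self, axis: int = -1):
        shifted = self.value - self.value.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_val = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_val).sum(axis=axis, keepdims=True)
            self._accumulate(out_val * (g - dot))

        return Tensor(out_val, parents=(self,), backward=bw)

    def gather(self, idx: np.ndarray) -> "Tensor":
        """Index the second axis of a (B, P, C) tensor with idx (B, Q[, K]).

        Returns (B, Q, C) or (B, Q, K, C).
        """
        B = self.value.shape[0]
        batch = np.arange(B).reshape((B,) + (1,) * (idx.ndim - 1))
        out_val = self.value[batch, idx]

        def bw(g):
            full = np.zeros_like(self.value)
            np.add.at(full, (batch, idx), g)
            self._accumulate(full)

        return Tensor(out_val, parents=(self,), backward=bw)

    @staticmethod
    def concatenate(tensors: list["Tensor"], axis: int = -1) -> "Tensor":
        vals = [t.value for t in tensors]
        out_val = np.concatenate(vals, axis=axis)
        sizes = [v.shape[axis] for v in vals]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)

        return Tensor(out_val, parents=tuple(tensors), backward=bw)

    # -- task-specific node ---------------------------------------------------

    def chamfer_to(self, target: np.ndarray) -> "Tensor":
        """Symmetric squared-distance Chamfer loss of a (B, N, 3) prediction
        against a constant (B, M, 3) target, averaged over the batch.

        Nearest neighbors are found with a KD-tree and held fixed in the
        backward pass.
        """
        pred = self.value
        B = pred.shape[0]
        total = 0.0
        grads = np.zeros_like(pred)
        for b in range(B):
            p, q = pred[b], target[b]
            tree_q = cKDTree(q)
            d_pq, j_pq = tree_q.query(p)
            tree_p = cKDTree(p)
            d_qp, j_qp = tree_p.query(q)
            total += (d_pq**2).mean() + (d_qp**2).mean()
            grads[b] += 2.0 * (p - q[j_pq]) / len(p)
            np.add.at(grads[b], j_qp, 2.0 * (p[j_qp] - q) / len(q))

        def bw(g):
            self._accumulate(g * grads / B)

        return Tensor(total / B, parents=(self,), backward=bw)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
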