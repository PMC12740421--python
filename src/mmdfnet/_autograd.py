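"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the primitives the package's networks need (dense and
convolutional layers, softmax/log-sum-exp losses, L2 normalization, and the
explicit input-gradient chains used by the critic's gradient penalty).
All tensors are float64; gradients accumulate into ``Tensor.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "logsumexp", "relu", "sigmoid"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(x)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _acc(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
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

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._acc(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * (other ** -1.0)

    def __rtruediv__(self, other):
        return _as_tensor(other) * (self ** -1.0)

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e

        def backward(g):
            if self.requires_grad:
                self._acc(g * e * self.data ** (e - 1.0))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._acc(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._acc(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), backward)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        in_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._acc(g.reshape(in_shape))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._acc(g.transpose(inv))

        return self._make(out_data, (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def take_cols(self, idx):
        """Select columns of a 2-D tensor (gather; backward scatter-adds)."""
        idx = np.asarray(idx)
        out_data = self.data[:, idx]
        in_shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                full = np.zeros(in_shape)
                np.add.at(full, (slice(None), idx), g)
                self._acc(full)

        return self._make(out_data, (self,), backward)

    def gather(self, index_arrays):
        """Advanced indexing by a tuple of integer arrays (used by im2col)."""
        out_data = self.data[index_arrays]
        in_shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                full = np.zeros(in_shape)
                np.add.at(full, index_arrays, g)
                self._acc(full)

        return self._make(out_data, (self,), backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        in_shape = self.data.shape

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._acc(np.broadcast_to(g, in_shape).copy())
                return
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            if not keepdims:
                g = np.expand_dims(g, tuple(a % len(in_shape) for a in axes))
            self._acc(np.broadcast_to(g, in_shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities --------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._acc(g * mask)

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._acc(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._acc(g / self.data)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._acc(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)


def relu(t: Tensor) -> Tensor:
    return _as_tensor(t).relu()


def sigmoid(t: Tensor) -> Tensor:
    return _as_tensor(t).sigmoid()


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._acc(piece)

        out._backward = backward
    return out


def logsumexp(t: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp along ``axis`` (max treated as constant)."""
    t = _as_tensor(t)
    m = t.data.max(axis=axis, keepdims=True)
    shifted = t - Tensor(m)
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    if not keepdims:
        out = out.reshape(np.squeeze(out.data, axis=axis).shape)
    return out
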