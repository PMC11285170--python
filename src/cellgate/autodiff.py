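"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the annotation model needs: affine maps,
ReLU/sigmoid/log-softmax nonlinearities, elementwise arithmetic, reductions,
``detach`` (stop-gradient) and ``grad_scale`` (identity forward, gradient
multiplied by a constant — the gradient-reversal layer is ``grad_scale(-lam)``).

All floating work is float32 by default; gradients are accumulated in the
same dtype. Gradient correctness is validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _to_array(value, dtype=DTYPE) -> np.ndarray:
    arr = np.asarray(value)
    if arr.dtype != dtype:
        arr = arr.astype(dtype)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting NumPy broadcasting."""
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
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # so ndarray + Tensor defers to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = _to_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

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

    # -- autodiff core --------------------------------------------------------

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (scalar unless `grad` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self.grad = _to_array(grad)
        for node in reversed(_toposort(self)):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(_to_array(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    # -- ops ------------------------------------------------------------------

    def __add__(self, other):
        other = ensure_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-ensure_tensor(other))

    def __rsub__(self, other):
        return ensure_tensor(other) + (-self)

    def __mul__(self, other):
        other = ensure_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = ensure_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2))

        return self._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = ensure_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    def square(self):
        def backward(g):
            self._accum(2.0 * self.data * g)

        return self._make(self.data ** 2, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = _sigmoid(self.data)

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        logsumexp = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - logsumexp
        softmax = np.exp(out_data)

        def backward(g):
            self._accum(g - softmax * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed only where unclamped."""
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            self._accum(g * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    def sum(self, axis=None):
        out_data = self.data.sum(axis=axis)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                self._accum(np.broadcast_to(np.expand_dims(g, axis), self.data.shape))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(self.data[idx], (self,), backward)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def grad_scale(self, factor: float) -> "Tensor":
        """Identity in the forward pass; multiplies the gradient by `factor`.

        `grad_scale(-lam)` is a gradient-reversal layer with coefficient lam.
        """

        def backward(g):
            self._accum(g * factor)

        return self._make(self.data.copy(), (self,), backward)


def ensure_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _toposort(root: Tensor) -> list:
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent in node._parents:
            stack.append((parent, False))
    return order
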