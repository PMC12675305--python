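"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based autodiff core sufficient for the dense and graph
autoencoders used by the clustering model: elementwise arithmetic with
broadcasting, matrix products, LeakyReLU/sigmoid/exponential/log
nonlinearities, row softmax, reductions, and an AdamW-style optimizer with
decoupled weight decay. Gradients are exact (verified against central finite
differences in the test suite).

Only float64 arrays are handled; all randomness (parameter init, dropout
masks) lives outside the engine so that a single integer seed controls it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "AdamW"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph: a value, its gradient, and a backward rule."""

    __slots__ = ("value", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ utils
    @property
    def shape(self):
        return self.value.shape

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _node(value, parents, backward) -> "Tensor":
        out = Tensor(value)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(g, self.value.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out = self._node(self.value + other.value, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._node(-self.value, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = self._node(self.value * other.value, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.value)
            if other.requires_grad:
                other._accum(g * self.value)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = self._node(self.value / other.value, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.value)
            if other.requires_grad:
                other._accum(-g * self.value / other.value**2)

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)
        out = self._node(self.value @ other.value, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.value.T)
            if other.requires_grad:
                other._accum(self.value.T @ g)

        out._backward = backward
        return out

    def pow(self, exponent: float):
        out = self._node(self.value**exponent, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.value ** (exponent - 1))

        out._backward = backward
        return out

    # ------------------------------------------------------------ structural
    @property
    def T(self):
        out = self._node(self.value.T, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g.T)

        out._backward = backward
        return out

    def sum(self, axis=None, keepdims=False):
        out = self._node(self.value.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.value.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ---------------------------------------------------------- nonlinearity
    def leaky_relu(self, slope: float = 0.01):
        mask = np.where(self.value > 0, 1.0, slope)
        out = self._node(self.value * mask, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = backward
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.value))
        out = self._node(s, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = backward
        return out

    def exp(self):
        e = np.exp(self.value)
        out = self._node(e, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * e)

        out._backward = backward
        return out

    def log(self):
        out = self._node(np.log(self.value), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.value)

        out._backward = backward
        return out

    def softmax_rows(self):
        """Numerically stable softmax along the last axis."""
        shifted = self.value - self.value.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=-1, keepdims=True)
        out = self._node(s, (self,), None)

        def backward(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=-1, keepdims=True)
                self._accum(s * (g - dot))

        out._backward = backward
        return out

    # -------------------------------------------------------------- backward
    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep graphs must not hit the recursion limit
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class AdamW:
    """Adam with decoupled L2 weight decay.

    `decay_mask` marks which parameters receive weight decay (biases and
    cluster centroids conventionally do not).
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, decay_mask: list[bool] | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decay_mask = decay_mask if decay_mask is not None else [True] * len(params)
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

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
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and self.decay_mask[i]:
                p.value -= self.lr * self.weight_decay * p.value
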