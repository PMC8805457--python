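"""Minimal vectorized reverse-mode automatic differentiation.

The networks in this package are small dense multilayer perceptrons with a
handful of custom loss terms (kernel MMD, hinge, GAN cross-entropy), so the
op set is deliberately tiny: elementwise arithmetic with numpy broadcasting,
matrix multiplication, a few nonlinearities, and axis reductions.  Values are
float64 numpy arrays; graphs are built define-by-run and freed after each
backward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "as_tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes numpy broadcast to produce it from `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("value", "grad", "_parents", "_backward")

    def __init__(self, value, _parents=(), _backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.value.shape

    # ---- graph construction helpers -------------------------------------

    def _binary(self, other, out_val, grad_self, grad_other):
        other = as_tensor(other)

        def backward(g):
            return (
                _unbroadcast(grad_self(g), self.value.shape),
                _unbroadcast(grad_other(g), other.value.shape),
            )

        return Tensor(out_val(other), (self, other), backward)

    # ---- arithmetic ------------------------------------------------------

    def __add__(self, other):
        return self._binary(other, lambda o: self.value + o.value,
                            lambda g: g, lambda g: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda o: self.value - o.value,
                            lambda g: g, lambda g: -g)

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self.value, other.value

        def backward(g):
            return (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape))

        return Tensor(a * b, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self.value, other.value

        def backward(g):
            return (_unbroadcast(g / b, a.shape),
                    _unbroadcast(-g * a / (b * b), b.shape))

        return Tensor(a / b, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return Tensor(-self.value, (self,), lambda g: (-g,))

    def __pow__(self, p: float):
        a = self.value
        return Tensor(a ** p, (self,), lambda g: (g * p * a ** (p - 1),))

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.value, other.value

        def backward(g):
            return (g @ b.T, a.T @ g)

        return Tensor(a @ b, (self, other), backward)

    # ---- elementwise nonlinearities -------------------------------------

    def exp(self):
        out = np.exp(self.value)
        return Tensor(out, (self,), lambda g: (g * out,))

    def log(self):
        a = self.value
        return Tensor(np.log(a), (self,), lambda g: (g / a,))

    def sqrt(self):
        out = np.sqrt(self.value)
        return Tensor(out, (self,), lambda g: (g / (2.0 * out),))

    def tanh(self):
        out = np.tanh(self.value)
        return Tensor(out, (self,), lambda g: (g * (1.0 - out * out),))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.value))
        return Tensor(out, (self,), lambda g: (g * out * (1.0 - out),))

    def relu(self):
        mask = self.value > 0
        return Tensor(self.value * mask, (self,), lambda g: (g * mask,))

    def clip(self, lo: float, hi: float):
        mask = (self.value > lo) & (self.value < hi)
        return Tensor(np.clip(self.value, lo, hi), (self,),
                      lambda g: (g * mask,))

    # ---- reductions / reshaping -----------------------------------------

    def sum(self, axis=None, keepdims=False):
        a = self.value

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.shape).copy(),)

        return Tensor(a.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        a = self.value
        n = a.size if axis is None else a.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self.value
        return Tensor(a.reshape(*shape), (self,),
                      lambda g: (g.reshape(a.shape),))

    @property
    def T(self):
        return Tensor(self.value.T, (self,), lambda g: (g.T,))

    # ---- backward pass ---------------------------------------------------

    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.value)
                parent.grad = parent.grad + g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    vals = [t.value for t in tensors]
    sizes = [v.shape[axis] for v in vals]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate(vals, axis=axis), tuple(tensors), backward)


class Adam:
    """Adaptive-moment SGD over a list of parameter Tensors (in-place)."""

    def __init__(self, params: list[Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
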