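"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the network and losses need: affine maps,
the activations (tanh, selu, sin, cos), softmax cross-entropy pieces
(exp, log, clamp), reductions, concatenation and row gathering.  Gradients
are accumulated by topological-order backpropagation.  Broadcasting is
supported for elementwise ops; gradients are un-broadcast by summation.
"""

from __future__ import annotations

import numpy as np

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient slot and a backward closure."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def T(self) -> "Tensor":
        return transpose(self)

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # -- operators ------------------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    def __radd__(self, other):
        return add(as_tensor(other), self)

    def __sub__(self, other):
        return add(self, neg(as_tensor(other)))

    def __rsub__(self, other):
        return add(as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    def __rmul__(self, other):
        return mul(as_tensor(other), self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    # -- backward pass ---------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.value)
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    order.append(n)
                    continue
                if id(n) in seen:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(value, parents, backward) -> Tensor:
    out = Tensor(value)
    if any(p.requires_grad or p._backward is not None for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- primitive ops -------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    v = a.value + b.value
    return _make(v, (a, b), lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def neg(a: Tensor) -> Tensor:
    return _make(-a.value, (a,), lambda g: (-g,))


def mul(a: Tensor, b: Tensor) -> Tensor:
    v = a.value * b.value
    return _make(
        v,
        (a, b),
        lambda g: (_unbroadcast(g * b.value, a.shape), _unbroadcast(g * a.value, b.shape)),
    )


def power(a: Tensor, p: float) -> Tensor:
    v = a.value ** p
    return _make(v, (a,), lambda g: (g * p * a.value ** (p - 1),))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    v = a.value @ b.value
    return _make(v, (a, b), lambda g: (g @ b.value.T, a.value.T @ g))


def transpose(a: Tensor) -> Tensor:
    return _make(a.value.T, (a,), lambda g: (g.T,))


def tanh(a: Tensor) -> Tensor:
    v = np.tanh(a.value)
    return _make(v, (a,), lambda g: (g * (1.0 - v * v),))


def selu(a: Tensor) -> Tensor:
    x = a.value
    pos = x > 0
    v = _SELU_SCALE * np.where(pos, x, _SELU_ALPHA * (np.exp(np.minimum(x, 0.0)) - 1.0))

    def back(g):
        d = _SELU_SCALE * np.where(pos, 1.0, _SELU_ALPHA * np.exp(np.minimum(x, 0.0)))
        return (g * d,)

    return _make(v, (a,), back)


def relu(a: Tensor) -> Tensor:
    v = np.maximum(a.value, 0.0)
    return _make(v, (a,), lambda g: (g * (a.value > 0),))


def sin(a: Tensor) -> Tensor:
    return _make(np.sin(a.value), (a,), lambda g: (g * np.cos(a.value),))


def cos(a: Tensor) -> Tensor:
    return _make(np.cos(a.value), (a,), lambda g: (-g * np.sin(a.value),))


def exp(a: Tensor) -> Tensor:
    v = np.exp(a.value)
    return _make(v, (a,), lambda g: (g * v,))


def log(a: Tensor, floor: float | None = None) -> Tensor:
    """Natural log; with `floor`, inputs are clamped below at `floor`
    (gradient is zero where the clamp is active)."""
    if floor is None:
        x = a.value
        return _make(np.log(x), (a,), lambda g: (g / x,))
    active = a.value >= floor
    x = np.maximum(a.value, floor)
    return _make(np.log(x), (a,), lambda g: (g * active / x,))


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    v = a.value.sum(axis=axis, keepdims=keepdims)

    def back(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).copy(),)

    return _make(v, (a,), back)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.value.size if axis is None else a.value.shape[axis]
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    v = np.concatenate([t.value for t in tensors], axis=axis)
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(v, tuple(tensors), back)


def gather_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows (duplicates allowed); gradient scatters with accumulation."""
    idx = np.asarray(idx)
    v = a.value[idx]

    def back(g):
        out = np.zeros_like(a.value)
        np.add.at(out, idx, g)
        return (out,)

    return _make(v, (a,), back)


def softmax(a: Tensor) -> Tensor:
    """Row-wise softmax, numerically stabilised."""
    x = a.value
    m = x.max(axis=-1, keepdims=True)
    e = np.exp(x - m)
    v = e / e.sum(axis=-1, keepdims=True)

    def back(g):
        dot = (g * v).sum(axis=-1, keepdims=True)
        return (v * (g - dot),)

    return _make(v, (a,), back)


class Adam:
    """Adaptive-moment stochastic gradient descent with gradient clipping."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = 5.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.value)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
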