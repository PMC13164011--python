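"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical engine behind :mod:`frostgrip.models`: a small tape
of :class:`Tensor` nodes supporting the operations the tactile-fusion
networks need (broadcasted arithmetic, batched matmul, softmax, slicing,
reshape/transpose, reductions) plus an Adam optimizer. Gradients are
accumulated by reverse topological sweep; broadcasting is undone by
summing over the broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "concat",
    "stack_last",
    "softmax",
    "softmax_cross_entropy",
    "glorot_uniform",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that were broadcast to reach its shape."""
    # strip leading added dims
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction helpers -------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # ---- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(out):
            if self.requires_grad:
                self._accum(-out.grad)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other.power(-1.0)

    def power(self, p: float):
        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1.0))

        return Tensor._make(self.data**p, (self,), backward)

    def exp(self):
        val = np.exp(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * val)

        return Tensor._make(val, (self,), backward)

    def tanh(self):
        val = np.tanh(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * (1.0 - val * val))

        return Tensor._make(val, (self,), backward)

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * val * (1.0 - val))

        return Tensor._make(val, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    # ---- linear algebra --------------------------------------------------

    def matmul(self, other: "Tensor"):
        """Batched matrix product (leading axes broadcast as numpy does)."""

        def backward(out):
            if self.requires_grad:
                g = out.grad @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                g = np.swapaxes(self.data, -1, -2) @ out.grad
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # ---- shape ops -------------------------------------------------------

    def reshape(self, *shape):
        old = self.shape

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.transpose(*inv))

        return Tensor._make(self.data.transpose(*axes), (self,), backward)

    def slice_axis1(self, start: int, stop: int):
        """Take x[:, start:stop, ...] keeping the axis."""

        def backward(out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                g[:, start:stop] = out.grad
                self._accum(g)

        return Tensor._make(self.data[:, start:stop], (self,), backward)

    def step_axis1(self, t: int):
        """Take x[:, t, ...] dropping the axis (one time step of a batch)."""

        def backward(out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                g[:, t] = out.grad
                self._accum(g)

        return Tensor._make(self.data[:, t], (self,), backward)

    # ---- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(out):
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- autodiff driver -------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node)


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    ax = axis if axis >= 0 else datas[0].ndim + axis
    sizes = [d.shape[ax] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(out):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[ax] = slice(a, b)
                t._accum(out.grad[tuple(idx)])

    out = Tensor(np.concatenate(datas, axis=ax))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def stack_last(tensors: list[Tensor]) -> Tensor:
    """Stack equal-shape tensors along a new trailing axis."""

    def backward(out):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(out.grad[..., i])

    out = Tensor(np.stack([t.data for t in tensors], axis=-1))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    val = e / e.sum(axis=axis, keepdims=True)

    def backward(out):
        if x.requires_grad:
            dot = (out.grad * val).sum(axis=axis, keepdims=True)
            x._accum(val * (out.grad - dot))

    return Tensor._make(val, (x,), backward)


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean cross-entropy over the batch; numerically stable fused op."""
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    n = logits.data.shape[0]
    loss = -(onehot * logp).sum() / n

    def backward(out):
        if logits.requires_grad:
            p = np.exp(logp)
            logits._accum(out.grad * (p - onehot) / n)

    return Tensor._make(loss, (logits,), backward)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer over a flat list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad**2
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
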