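"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical core behind the embedding pre-training and the
path-attention scorer: a :class:`Tensor` wraps an ``ndarray`` and records
the operations applied to it; :meth:`Tensor.backward` accumulates gradients
by reverse topological traversal.  Only the operations the package needs are
implemented (elementwise arithmetic, matmul, common nonlinearities, reductions
with axis support, concatenation, fancy-index gather with scatter-add
backward, softmax).  Broadcasting follows numpy semantics; gradients of
broadcast operands are summed back to the operand shape.

All arrays are float64.  The engine is intentionally eager and single
threaded; the model sizes here (thousands of parameters, batches of a few
thousand rows) do not warrant more machinery.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "take", "softmax", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape* (reversing numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))
        return self._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accum(-g)
        return self._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))
        return self._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        p = float(exponent)

        def bw(g):
            a._accum(g * p * a.data ** (p - 1.0))
        return self._make(a.data ** p, (a,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))
        return self._make(a.data @ b.data, (a, b), bw)

    # -- nonlinearities ---------------------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accum(g * out_data)
        return self._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accum(g / a.data)
        return self._make(np.log(a.data), (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accum(g * mask)
        return self._make(a.data * mask, (a,), bw)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bw(g):
            a._accum(g * (1.0 - out_data ** 2))
        return self._make(out_data, (a,), bw)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))

        def bw(g):
            a._accum(g * out_data * (1.0 - out_data))
        return self._make(out_data, (a,), bw)

    def softplus(self):
        """log(1 + exp(x)), numerically stable; gradient is sigmoid(x)."""
        a = self
        out_data = np.logaddexp(0.0, a.data)

        def bw(g):
            a._accum(g / (1.0 + np.exp(-np.clip(a.data, -500, 500))))
        return self._make(out_data, (a,), bw)

    # -- reductions / shaping --------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy())
        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along *axis*; subgradient routed to the (first) argmax."""
        a = self
        idx = np.argmax(a.data, axis=axis)
        out_data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis)

        def bw(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            full = np.zeros_like(a.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), gg, axis)
            a._accum(full)
        return self._make(out_data, (a,), bw)

    def reshape(self, *shape):
        a = self
        orig = a.shape

        def bw(g):
            a._accum(g.reshape(orig))
        return self._make(a.data.reshape(*shape), (a,), bw)

    def __getitem__(self, key):
        a = self
        key_parts = key if isinstance(key, tuple) else (key,)
        fancy = any(isinstance(k, (np.ndarray, list)) for k in key_parts)

        def bw(g):
            full = np.zeros_like(a.data)
            if fancy:
                np.add.at(full, key, g)
            else:  # basic indexing selects disjoint elements
                full[key] += g
            a._accum(full)
        return self._make(a.data[key], (a,), bw)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, bw)


def take(t: Tensor, indices, axis: int = 0) -> Tensor:
    """Row gather with scatter-add backward (embedding lookup)."""
    indices = np.asarray(indices)
    a = t

    def bw(g):
        full = np.zeros_like(a.data)
        if axis == 0:
            np.add.at(full, indices, g)
        else:  # pragma: no cover - only axis 0 used
            raise NotImplementedError
        a._accum(full)
    return Tensor._make(np.take(a.data, indices, axis=axis), (a,), bw)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax built from primitive ops."""
    shifted = t - Tensor(np.max(t.data, axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
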