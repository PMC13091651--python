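"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The trainable parts of the pipeline (attention fusion, graph convolutions,
the global-exchange layer, and the scoring MLP) are small dense computations
on matrices of at most a few thousand entries, so a lightweight tape-based
engine is sufficient and keeps the package free of heavyweight deep-learning
dependencies.

Only the operations actually used by the model are implemented.  All
arrays are float64 and all tensors with ``requires_grad`` accumulate
gradients of a scalar loss after :meth:`Tensor.backward`.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "bce_with_logits", "glorot"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, inverting NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, n in enumerate(shape):
        if n == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus the tape machinery for reverse-mode gradients."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents: Sequence["Tensor"],
                 backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        data = self.data + other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._from_op(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            self._accumulate(-g)

        return self._from_op(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        data = self.data * other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._from_op(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float) -> "Tensor":
        return self * (1.0 / float(scalar))

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)
        if self.ndim < 2 or other.ndim < 2:
            raise ValueError("matmul requires tensors with ndim >= 2")
        data = self.data @ other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                ga = g @ other.data.swapaxes(-1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = self.data.swapaxes(-1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return self._from_op(data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------

    def transpose_last(self) -> "Tensor":
        """Swap the last two axes."""
        data = self.data.swapaxes(-1, -2)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g.swapaxes(-1, -2))

        return self._from_op(data, (self,), backward)

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.shape
        data = self.data.reshape(*shape)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g.reshape(orig))

        return self._from_op(data, (self,), backward)

    def take_rows(self, indices) -> "Tensor":
        """Gather rows along axis 0; gradient scatter-adds duplicates."""
        idx = np.asarray(indices, dtype=np.intp)
        data = self.data[idx]

        def backward(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return self._from_op(data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray) -> None:
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return self._from_op(data, (self,), backward)

    def mean(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def pow(self, exponent: float) -> "Tensor":
        """Elementwise power for a constant exponent (data must stay > 0
        when the exponent is fractional)."""
        data = self.data ** exponent

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return self._from_op(data, (self,), backward)

    def normalize_rows(self, eps: float = 1e-8) -> "Tensor":
        """Scale each row (last axis) to unit L2 norm."""
        sq = (self * self).sum(axis=-1, keepdims=True)
        return self * (sq + eps).pow(-0.5)

    # -- nonlinearities -------------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        data = self.data * mask

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * mask)

        return self._from_op(data, (self,), backward)

    def tanh(self) -> "Tensor":
        data = np.tanh(self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * (1.0 - data * data))

        return self._from_op(data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        data = _sigmoid(self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * data * (1.0 - data))

        return self._from_op(data, (self,), backward)

    def softmax_last(self) -> "Tensor":
        """Row-wise softmax over the last axis."""
        shifted = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        data = e / e.sum(axis=-1, keepdims=True)

        def backward(g: np.ndarray) -> None:
            inner = (g * data).sum(axis=-1, keepdims=True)
            self._accumulate(data * (g - inner))

        return self._from_op(data, (self,), backward)

    def dropout(self, p: float, rng: np.random.Generator,
                training: bool = True) -> "Tensor":
        if not training or p <= 0.0:
            return self
        mask = (rng.random(self.shape) >= p) / (1.0 - p)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * mask)

        return self._from_op(self.data * mask, (self,), backward)

    # -- backward pass --------------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient splitting."""
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._from_op(data, tensors, backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    t = np.asarray(targets, dtype=np.float64)
    x = logits.data
    if x.shape != t.shape:
        raise ValueError(f"shape mismatch: logits {x.shape} vs targets {t.shape}")
    loss = np.maximum(x, 0.0) - x * t + np.log1p(np.exp(-np.abs(x)))
    n = max(x.size, 1)

    def backward(g: np.ndarray) -> None:
        logits._accumulate(g * (_sigmoid(x) - t) / n)

    return Tensor._from_op(loss.sum() / n, (logits,), backward)


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> Tensor:
    """Glorot-uniform initialized trainable matrix."""
    limit = np.sqrt(6.0 / (n_in + n_out))
    return Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)),
                  requires_grad=True)


class Adam:
    """Adam optimizer over a fixed list of parameters."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
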