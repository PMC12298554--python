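"""Compact reverse-mode automatic differentiation on numpy arrays.

Everything trainable in this package (recurrent encoders, relational graph
convolution, graph attention, the regression head and the concordance loss)
is expressed with the ``Tensor`` operations below, so one backward pass
delivers exact float64 gradients for every parameter.  The op set is the
minimum the model needs: broadcasting arithmetic, matmul, the usual
pointwise nonlinearities, reductions, concat/stack, row gathering and
segment sums (the scatter-add primitive behind edge-wise message passing
and per-neighborhood softmax normalisation).

Design constraints:
  * float64 throughout — finite-difference gradient checks at 1e-4..1e-6
    tolerances are part of the package's test contract;
  * graphs are built only when gradients can flow (``requires_grad``
    propagates from leaves; ``no_grad()`` disables taping for evaluation).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph taping (evaluation mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
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

    def numpy(self) -> np.ndarray:
        return np.array(self.data)

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor without gradient tape")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without seed gradient requires a scalar")
            grad = np.ones_like(self.data)
        # iterative topological order (graphs can be thousands of nodes deep
        # along the recurrent time axis; recursion would overflow)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                # leaf: accumulate into .grad
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
        # note: interior nodes do not retain .grad

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        o = self._coerce(other)
        data = self.data + o.data
        return Tensor._make(data, (self, o), lambda g: (
            (self, _unbroadcast(g, self.data.shape)),
            (o, _unbroadcast(g, o.data.shape))))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        o = self._coerce(other)
        data = self.data * o.data
        return Tensor._make(data, (self, o), lambda g: (
            (self, _unbroadcast(g * o.data, self.data.shape)),
            (o, _unbroadcast(g * self.data, o.data.shape))))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        data = self.data / o.data
        return Tensor._make(data, (self, o), lambda g: (
            (self, _unbroadcast(g / o.data, self.data.shape)),
            (o, _unbroadcast(-g * self.data / (o.data ** 2), o.data.shape))))

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):
            raise TypeError("only scalar exponents are supported")
        data = self.data ** exponent
        return Tensor._make(data, (self,), lambda g: (
            (self, g * exponent * self.data ** (exponent - 1)),))

    def __matmul__(self, other):
        o = self._coerce(other)
        data = self.data @ o.data
        def backward(g):
            return ((self, g @ o.data.swapaxes(-1, -2)),
                    (o, self.data.swapaxes(-1, -2) @ g))
        return Tensor._make(data, (self, o), backward)

    # -- pointwise nonlinearities --------------------------------------------

    def exp(self):
        data = np.exp(self.data)
        return Tensor._make(data, (self,), lambda g: ((self, g * data),))

    def log(self):
        return Tensor._make(np.log(self.data), (self,),
                            lambda g: ((self, g / self.data),))

    def sqrt(self):
        data = np.sqrt(self.data)
        return Tensor._make(data, (self,), lambda g: ((self, g * 0.5 / data),))

    def tanh(self):
        data = np.tanh(self.data)
        return Tensor._make(data, (self,), lambda g: ((self, g * (1.0 - data ** 2)),))

    def sigmoid(self):
        data = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # numerically stable
        return Tensor._make(data, (self,), lambda g: ((self, g * data * (1.0 - data)),))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: ((self, g * mask),))

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)
        return Tensor._make(self.data * factor, (self,), lambda g: ((self, g * factor),))

    # -- reductions / reshaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)
        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.data.shape).copy()),)
        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: ((self, g.reshape(old)),))

    @property
    def T(self):
        return Tensor._make(self.data.T, (self,), lambda g: ((self, g.T),))

    # -- structural ops -------------------------------------------------------

    @staticmethod
    def concat(tensors: Sequence["Tensor"], axis: int = 0) -> "Tensor":
        ts = [Tensor._coerce(t) for t in tensors]
        data = np.concatenate([t.data for t in ts], axis=axis)
        sizes = [t.data.shape[axis] for t in ts]
        offsets = np.cumsum([0] + sizes)
        def backward(g):
            out = []
            for t, a, b in zip(ts, offsets[:-1], offsets[1:]):
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                out.append((t, g[tuple(idx)]))
            return tuple(out)
        return Tensor._make(data, ts, backward)

    @staticmethod
    def stack(tensors: Sequence["Tensor"], axis: int = 0) -> "Tensor":
        ts = [Tensor._coerce(t) for t in tensors]
        data = np.stack([t.data for t in ts], axis=axis)
        def backward(g):
            parts = np.moveaxis(g, axis, 0)
            return tuple((t, parts[i]) for i, t in enumerate(ts))
        return Tensor._make(data, ts, backward)

    def take_rows(self, index: np.ndarray) -> "Tensor":
        """Gather rows (axis 0) by integer index; scatter-adds on backward."""
        index = np.asarray(index, dtype=np.intp)
        data = self.data[index]
        def backward(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, index, g)
            return ((self, acc),)
        return Tensor._make(data, (self,), backward)

    def segment_sum(self, segment_ids: np.ndarray, num_segments: int) -> "Tensor":
        """Sum rows (axis 0) into ``num_segments`` buckets; gathers on backward."""
        ids = np.asarray(segment_ids, dtype=np.intp)
        out_shape = (num_segments,) + self.data.shape[1:]
        data = np.zeros(out_shape)
        np.add.at(data, ids, self.data)
        return Tensor._make(data, (self,), lambda g: ((self, g[ids]),))


# -- functional conveniences used across the model ---------------------------

def segment_softmax(logits: Tensor, segment_ids: np.ndarray,
                    num_segments: int) -> Tensor:
    """Softmax of a 1-D logit vector within each segment.

    The per-segment max is subtracted as a constant; the softmax is
    shift-invariant so the gradient is unaffected.
    """
    ids = np.asarray(segment_ids, dtype=np.intp)
    shift = np.full(num_segments, -np.inf)
    np.maximum.at(shift, ids, logits.data)
    z = (logits - Tensor(shift[ids])).exp()
    denom = z.segment_sum(ids, num_segments)
    return z / denom.take_rows(ids)


def segment_mean(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    ids = np.asarray(segment_ids, dtype=np.intp)
    counts = np.bincount(ids, minlength=num_segments).astype(np.float64)
    if np.any(counts == 0):
        raise ValueError("segment_mean: empty segment")
    total = x.segment_sum(ids, num_segments)
    if x.ndim > 1:
        counts = counts.reshape((-1,) + (1,) * (x.ndim - 1))
    return total / Tensor(counts)


class Adam:
    """Adam with optional L2 weight decay over a dict of parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m = self._m[key] = b1 * self._m[key] + (1 - b1) * g
            v = self._v[key] = b2 * self._v[key] + (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
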