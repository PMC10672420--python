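"""Minimal reverse-mode automatic differentiation on numpy arrays.

The super-resolution model in this package is small enough to train on a CPU,
so instead of depending on a deep-learning framework the package carries its
own scalar-graph-free autodiff core: a :class:`Tensor` wraps a float64
``numpy`` array and records, per operation, a closure that routes the upstream
gradient to its parents.  Only the operations the model needs are implemented
(broadcast arithmetic, ReLU, |x|, reductions, reshape/transpose/slice, row
gather, dense layers and 3x3 convolution).

Two determinism constraints shape the implementation:

* dense layers (`linear`) go through ``np.einsum`` rather than BLAS matmul,
  because einsum's reduction order over the contracted axis does not depend
  on the batch size — predictions are therefore bitwise identical no matter
  how queries are chunked;
* 3x3 convolution (`conv3x3`) is decomposed into nine shifted ``tensordot``
  contractions (BLAS-backed, fast); the encoder runs once per image, so its
  results never depend on query chunking.

Everything is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "take_rows",
    "relu",
    "absolute",
    "mean",
    "total",
    "linear",
    "conv3x3",
]


class Tensor:
    """A float64 numpy array with a gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery ------------------------------------------------------

    def _ensure_grad(self) -> np.ndarray:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        return self.grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this node; accumulates into ``.grad`` fields."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._ensure_grad()
        self.grad += np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar -------------------------------------------------------

    def __add__(self, other):
        return _add(self, as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return _add(self, _neg(as_tensor(other)))

    def __rsub__(self, other):
        return _add(as_tensor(other), _neg(self))

    def __neg__(self):
        return _neg(self)

    def __mul__(self, other):
        return _mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division by a Tensor is not supported")
        return _mul(self, as_tensor(1.0 / float(other)))

    def __getitem__(self, key):
        return _getitem(self, key)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return _reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return _transpose(self, axes)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- arithmetic ---------------------------------------------------------------


def _add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._ensure_grad()
            a.grad += _unbroadcast(g, a.data.shape)
        if b.requires_grad:
            b._ensure_grad()
            b.grad += _unbroadcast(g, b.data.shape)

    return _node(a.data + b.data, (a, b), backward)


def _neg(a: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._ensure_grad()
            a.grad -= g

    return _node(-a.data, (a,), backward)


def _mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._ensure_grad()
            a.grad += _unbroadcast(g * b.data, a.data.shape)
        if b.requires_grad:
            b._ensure_grad()
            b.grad += _unbroadcast(g * a.data, b.data.shape)

    return _node(a.data * b.data, (a, b), backward)


def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._ensure_grad()
            a.grad += g * mask

    return _node(np.where(mask, a.data, 0.0), (a,), backward)


def absolute(a: Tensor) -> Tensor:
    a = as_tensor(a)
    sign = np.sign(a.data)

    def backward(g):
        if a.requires_grad:
            a._ensure_grad()
            a.grad += g * sign

    return _node(np.abs(a.data), (a,), backward)


def total(a: Tensor) -> Tensor:
    """Sum over all elements -> scalar tensor."""
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a._ensure_grad()
            a.grad += np.broadcast_to(g, a.data.shape)

    return _node(np.asarray(a.data.sum()), (a,), backward)


def mean(a: Tensor) -> Tensor:
    a = as_tensor(a)
    n = a.data.size

    def backward(g):
        if a.requires_grad:
            a._ensure_grad()
            a.grad += np.broadcast_to(g / n, a.data.shape)

    return _node(np.asarray(a.data.mean()), (a,), backward)


# -- shape ops ----------------------------------------------------------------


def _reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape

    def backward(g):
        if a.requires_grad:
            a._ensure_grad()
            a.grad += g.reshape(old)

    return _node(a.data.reshape(shape), (a,), backward)


def _transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._ensure_grad()
            a.grad += g.transpose(inv)

    return _node(a.data.transpose(axes), (a,), backward)


def _getitem(a: Tensor, key) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._ensure_grad()
            # basic slicing only -> no repeated destinations
            a.grad[key] += g

    return _node(a.data[key], (a,), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._ensure_grad()
                t.grad += p

    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def take_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows of a 2-D tensor: output shape ``idx.shape + (D,)``.

    Backward scatters with ``np.add.at`` so repeated indices accumulate.
    """
    a = as_tensor(a)
    if a.data.ndim != 2:
        raise ValueError("take_rows expects a 2-D tensor of rows")
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g):
        if a.requires_grad:
            a._ensure_grad()
            np.add.at(a.grad, idx.ravel(),
                      g.reshape(-1, a.data.shape[1]))

    return _node(a.data[idx], (a,), backward)


# -- dense / conv layers ------------------------------------------------------


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """``y = x @ w (+ b)`` for 2-D ``x`` via einsum (chunk-size invariant)."""
    x, w = as_tensor(x), as_tensor(w)
    out = np.einsum("nk,kj->nj", x.data, w.data)
    if b is not None:
        b = as_tensor(b)
        out = out + b.data
        parents = (x, w, b)
    else:
        parents = (x, w)

    def backward(g):
        if x.requires_grad:
            x._ensure_grad()
            x.grad += np.einsum("nj,kj->nk", g, w.data)
        if w.requires_grad:
            w._ensure_grad()
            w.grad += np.einsum("nk,nj->kj", x.data, g)
        if b is not None and b.requires_grad:
            b._ensure_grad()
            b.grad += g.sum(axis=0)

    return _node(out, parents, backward)


def conv3x3(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded 3x3 convolution, NCHW layout.

    ``x``: (N, C, H, W); ``w``: (F, C, 3, 3); ``b``: (F,).
    Implemented as nine shifted (C -> F) contractions on the zero-padded
    input, which keeps both passes in BLAS without an im2col buffer.
    """
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.data.shape
    f = w.data.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((n, h, wd, f))
    for ki in range(3):
        for kj in range(3):
            # (N,C,H,W) x (C,F) -> (N,H,W,F)
            out += np.tensordot(xp[:, :, ki:ki + h, kj:kj + wd],
                                w.data[:, :, ki, kj], axes=([1], [1]))
    out = out.transpose(0, 3, 1, 2)
    if b is not None:
        b = as_tensor(b)
        out = out + b.data[None, :, None, None]
        parents = (x, w, b)
    else:
        parents = (x, w)

    def backward(g):
        # g: (N,F,H,W)
        if w.requires_grad:
            w._ensure_grad()
            for ki in range(3):
                for kj in range(3):
                    w.grad[:, :, ki, kj] += np.tensordot(
                        g, xp[:, :, ki:ki + h, kj:kj + wd],
                        axes=([0, 2, 3], [0, 2, 3]))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for ki in range(3):
                for kj in range(3):
                    # (N,F,H,W) x (F,C) -> (N,C,H,W) shifted
                    gxp[:, :, ki:ki + h, kj:kj + wd] += np.tensordot(
                        g, w.data[:, :, ki, kj],
                        axes=([1], [0])).transpose(0, 3, 1, 2)
            x._ensure_grad()
            x.grad += gxp[:, :, 1:-1, 1:-1]
        if b is not None and b.requires_grad:
            b._ensure_grad()
            b.grad += g.sum(axis=(0, 2, 3))

    return _node(out, parents, backward)
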