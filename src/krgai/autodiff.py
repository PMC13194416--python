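"""Compact reverse-mode automatic differentiation over numpy arrays.

The reasoning model needs gradients through a few dozen dense-algebra
primitives (batched matmul, gathers, segment reductions, elementwise
nonlinearities).  This module provides exactly those as a tape-based
:class:`Tensor` with `float64` storage — small enough to audit, fast
enough for the graph sizes this package targets, and fully deterministic
on one thread.

Only operations the model uses are implemented; shapes follow numpy
broadcasting, and gradients of broadcast operands are reduced back to the
operand's shape.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "gradcheck"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast from ``shape``."""
    if grad.shape == shape:
        return grad
    n_extra = grad.ndim - len(shape)
    if n_extra > 0:
        grad = grad.sum(axis=tuple(range(n_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], tuple] | None = None

    # -- plumbing --------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(
        data: np.ndarray,
        parents: Sequence["Tensor"],
        backward: Callable[[np.ndarray], tuple],
    ) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-accumulate gradients from this (typically scalar) node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar")
            grad = np.ones_like(self.data)
        # topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        a, b = self, other
        out = a.data + b.data
        return Tensor._make(
            out, (a, b),
            lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        a, b = self, other
        return Tensor._make(
            a.data * b.data, (a, b),
            lambda g: (
                _unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        a, b = self, other
        return Tensor._make(
            a.data / b.data, (a, b),
            lambda g: (
                _unbroadcast(g / b.data, a.shape),
                _unbroadcast(-g * a.data / (b.data ** 2), b.shape),
            ),
        )

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        a, b = self, other

        def back(g: np.ndarray):
            ga = _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape)
            gb = _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape)
            return ga, gb

        return Tensor._make(a.data @ b.data, (a, b), back)

    # -- elementwise nonlinearities --------------------------------------
    def exp(self) -> "Tensor":
        a = self
        out = np.exp(a.data)
        return Tensor._make(out, (a,), lambda g: (g * out,))

    def log(self) -> "Tensor":
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sigmoid(self) -> "Tensor":
        a = self
        out = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
        return Tensor._make(out, (a,), lambda g: (g * out * (1 - out),))

    def softplus(self) -> "Tensor":
        # log(1 + e^x), stable for large |x|
        a = self
        out = np.logaddexp(0.0, a.data)
        sig = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
        return Tensor._make(out, (a,), lambda g: (g * sig,))

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: (g * mask,))

    def leaky_relu(self, negative_slope: float = 0.01) -> "Tensor":
        a = self
        slope = np.where(a.data > 0, 1.0, negative_slope)
        return Tensor._make(a.data * slope, (a,), lambda g: (g * slope,))

    def elu(self, alpha: float = 1.0) -> "Tensor":
        a = self
        neg = alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0)
        out = np.where(a.data > 0, a.data, neg)
        deriv = np.where(a.data > 0, 1.0, neg + alpha)
        return Tensor._make(out, (a,), lambda g: (g * deriv,))

    # -- shape / reduction ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def back(g: np.ndarray):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, a.shape).copy(),)

        return Tensor._make(out, (a,), back)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        a = self
        out = a.data.reshape(*shape)
        return Tensor._make(out, (a,), lambda g: (g.reshape(a.shape),))

    def swapaxes(self, ax1: int, ax2: int) -> "Tensor":
        a = self
        return Tensor._make(
            np.swapaxes(a.data, ax1, ax2), (a,),
            lambda g: (np.swapaxes(g, ax1, ax2),),
        )

    def broadcast_to(self, shape: tuple[int, ...]) -> "Tensor":
        a = self
        return Tensor._make(
            np.broadcast_to(a.data, shape).copy(), (a,),
            lambda g: (_unbroadcast(g, a.shape),),
        )

    def expand_dims(self, axis: int) -> "Tensor":
        a = self
        return Tensor._make(
            np.expand_dims(a.data, axis), (a,),
            lambda g: (np.squeeze(g, axis=axis),),
        )

    def take(self, indices: np.ndarray, axis: int) -> "Tensor":
        """Gather rows along ``axis``; gradient scatter-adds back."""
        a = self
        idx = np.asarray(indices)
        out = np.take(a.data, idx, axis=axis)

        def back(g: np.ndarray):
            ga = np.zeros_like(a.data)
            sl: list = [slice(None)] * a.ndim
            sl[axis] = idx
            np.add.at(ga, tuple(sl), g)
            return (ga,)

        return Tensor._make(out, (a,), back)

    def segment_sum(
        self, segment_ids: np.ndarray, num_segments: int, axis: int
    ) -> "Tensor":
        """Sum entries with equal ``segment_ids`` along ``axis``.

        The gradient is a plain gather, so scatter cost is paid only in
        the forward pass.
        """
        a = self
        seg = np.asarray(segment_ids)
        shape = list(a.shape)
        shape[axis] = num_segments
        out = np.zeros(shape, dtype=np.float64)
        sl: list = [slice(None)] * a.ndim
        sl[axis] = seg
        np.add.at(out, tuple(sl), a.data)

        def back(g: np.ndarray):
            return (np.take(g, seg, axis=axis),)

        return Tensor._make(out, (a,), back)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate along ``axis``; gradient splits back."""
    tensors = [Tensor._lift(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g: np.ndarray):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out, tensors, back)


def gradcheck(
    fn: Callable[..., Tensor],
    inputs: Sequence[np.ndarray],
    eps: float = 1e-6,
    atol: float = 1e-5,
) -> bool:
    """Compare analytic gradients of ``sum(fn(*inputs))`` to central differences."""
    tensors = [Tensor(x, requires_grad=True) for x in inputs]
    out = fn(*tensors).sum()
    out.backward()
    for t, x in zip(tensors, inputs):
        num = np.zeros_like(np.asarray(x, dtype=np.float64))
        flat = num.reshape(-1)
        xflat = t.data.reshape(-1)
        for i in range(flat.size):
            orig = xflat[i]
            xflat[i] = orig + eps
            hi = fn(*[Tensor(u.data) for u in tensors]).sum().data
            xflat[i] = orig - eps
            lo = fn(*[Tensor(u.data) for u in tensors]).sum().data
            xflat[i] = orig
            flat[i] = (hi - lo) / (2 * eps)
        if not np.allclose(t.grad, num, atol=atol):
            return False
    return True
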