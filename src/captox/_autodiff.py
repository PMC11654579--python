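"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains its encoder on CPU with this engine: a :class:`Tensor`
wraps an ``ndarray`` and records, for every differentiable operation, a
closure that accumulates gradients into its parents. Calling
:meth:`Tensor.backward` on a scalar loss walks the tape in reverse
topological order.

Only the operations the toxicity model needs are implemented (elementwise
arithmetic, batched matmul, exp/log/tanh/relu, axis reductions, reshape /
swapaxes, a zero-filled sequence shift used by the depthwise convolution,
and an integer-index gather for embedding tables). Every op's gradient is
exercised by finite-difference checks in the test suite.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (inference mode); nests safely."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ utils
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            self.requires_grad and self._accum(_unbroadcast(g, self.data.shape))
            other.requires_grad and other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self.requires_grad and self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            self.requires_grad and self._accum(_unbroadcast(g * other.data, self.data.shape))
            other.requires_grad and other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        def backward(g):
            self.requires_grad and self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # ------------------------------------------------------------ nonlinearity
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self.requires_grad and self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self.requires_grad and self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self.requires_grad and self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), backward)

    def relu(self):
        def backward(g):
            self.requires_grad and self._accum(g * (self.data > 0))

        return self._make(np.maximum(self.data, 0.0), (self,), backward)

    # --------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=True)
        hot = (self.data == out_data).astype(np.float64)
        hot /= hot.sum(axis=axis, keepdims=True)  # split ties evenly

        def backward(g):
            if not self.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(gg * hot)

        return self._make(out_data if keepdims else out_data.squeeze(axis), (self,), backward)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        def backward(g):
            self.requires_grad and self._accum(g.reshape(self.data.shape))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            self.requires_grad and self._accum(np.swapaxes(g, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), backward)

    def shift(self, offset: int, axis: int = 1):
        """Shift along `axis` by `offset` positions, filling with zeros.

        ``shift(+1)`` moves entry i to i+1 (content slides right). Adjoint of
        a shift is the opposite shift, which is what backward applies.
        """
        out_data = _shift_array(self.data, offset, axis)

        def backward(g):
            self.requires_grad and self._accum(_shift_array(g, -offset, axis))

        return self._make(out_data, (self,), backward)

    def gather(self, idx: np.ndarray):
        """Index the first axis of a table with an integer array (embedding lookup)."""
        idx = np.asarray(idx)

        def backward(g):
            if not self.requires_grad:
                return
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx.reshape(-1), g.reshape(-1, self.data.shape[-1]))
            self._accum(acc)

        return self._make(self.data[idx], (self,), backward)

    # ---------------------------------------------------------------- backward
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep tapes would blow the recursion limit
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
                node._backward(node.grad)


def _shift_array(x: np.ndarray, offset: int, axis: int) -> np.ndarray:
    if offset == 0:
        return x.copy()
    out = np.zeros_like(x)
    n = x.shape[axis]
    if abs(offset) >= n:
        return out
    src = [slice(None)] * x.ndim
    dst = [slice(None)] * x.ndim
    if offset > 0:
        src[axis] = slice(0, n - offset)
        dst[axis] = slice(offset, n)
    else:
        src[axis] = slice(-offset, n)
        dst[axis] = slice(0, n + offset)
    out[tuple(dst)] = x[tuple(src)]
    return out


class Parameter(Tensor):
    """A trainable tensor; model code collects these for the optimizer."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
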