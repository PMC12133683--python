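"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the compute core of the package: a small tensor type recording a
directed acyclic graph of array operations, with enough primitives to express
1-D convolution, LSTM recurrences, criss-cross attention and an MLP head, and
to train them by gradient descent.  Gradients for every primitive are
validated against central finite differences in the test suite.

Only the operations the models need are implemented; there is no broadcasting
of gradients beyond numpy broadcasting semantics (reduced away correctly on
the backward pass), no in-place mutation of graph tensors, and no higher-order
differentiation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "einsum", "gather", "bce_with_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were of size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # keep numpy from hijacking left-operand dispatch

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- core protocol --------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, grad: np.ndarray, own: bool = False) -> None:
        """Accumulate a gradient contribution.

        ``own=True`` promises ``grad`` is a freshly allocated array no other
        node holds, so it can be stored without a defensive copy; shared or
        view gradients (from add/reshape/transpose/concat) are copied on
        first storage because later accumulations modify the buffer in place.
        """
        if self.grad is None:
            if own and grad.dtype == np.float64 and grad.flags.owndata:
                self.grad = grad
            else:
                self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs include long LSTM chains
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape), own=True)
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape), own=True)

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape), own=True)
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape), own=True
                )

        return Tensor._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.expand_dims(g, -1) * other.data
                else:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape), own=True)
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.expand_dims(self.data, -1) * np.expand_dims(g, -2)
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape), own=True)

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data), own=True)

        return Tensor._make(out_data, (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2), own=True)

        return Tensor._make(out_data, (self,), backward)

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0), own=True)

        return Tensor._make(out_data, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data, own=True)

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data, own=True)

        return Tensor._make(np.log(self.data), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy(), own=True)
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy(), own=True)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        # ties split gradient equally between maximal entries
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(mask * g / counts, own=True)

        return Tensor._make(
            out_data if keepdims else out_data.squeeze(axis), (self,), backward
        )

    def softmax(self, axis: int) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - dot), own=True)

        return Tensor._make(out_data, (self,), backward)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def flip(self, axis: int) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(np.flip(g, axis=axis))

        return Tensor._make(np.flip(self.data, axis=axis), (self,), backward)

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]
        basic = isinstance(key, (int, slice)) or (
            isinstance(key, tuple)
            and all(isinstance(k, (int, slice)) for k in key)
        )

        def backward(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                if basic:  # basic indexing never aliases; += is exact
                    gx[key] += g
                else:
                    np.add.at(gx, key, g)
                self._accum(gx, own=True)

        return Tensor._make(out_data, (self,), backward)


# -- free functions -----------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis), own=True)

    return Tensor._make(out_data, tuple(tensors), backward)


def einsum(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum.

    Restricted to contraction-style specs where every input index also appears
    in the output or in the other operand (no traces/diagonals), which makes
    each operand's gradient itself an einsum with operands swapped.
    """
    a, b = Tensor.as_tensor(a), Tensor.as_tensor(b)
    inputs, out_spec = spec.replace(" ", "").split("->")
    a_spec, b_spec = inputs.split(",")
    for s, other in ((a_spec, b_spec), (b_spec, a_spec)):
        if len(set(s)) != len(s):
            raise ValueError(f"repeated index within one operand: {spec!r}")
        if not set(s) <= set(out_spec) | set(other):
            raise ValueError(f"index lost from both output and partner: {spec!r}")
    out_data = np.einsum(spec, a.data, b.data, optimize=True)

    def backward(g):
        if a.requires_grad:
            a._accum(np.einsum(f"{out_spec},{b_spec}->{a_spec}", g, b.data,
                               optimize=True), own=True)
        if b.requires_grad:
            b._accum(np.einsum(f"{out_spec},{a_spec}->{b_spec}", g, a.data,
                               optimize=True), own=True)

    return Tensor._make(out_data, (a, b), backward)


def gather(x: Tensor, index: np.ndarray, axis: int) -> Tensor:
    """Pick entries of ``x`` along ``axis`` with an integer index array.

    ``index`` must be broadcastable to the output shape, which equals the
    shape of ``x`` with ``axis`` replaced by the index extent.  The backward
    pass scatter-adds into the picked positions.
    """
    x = Tensor.as_tensor(x)
    out_shape = list(x.shape)
    idx = np.asarray(index)
    out_shape[axis] = idx.shape[axis] if idx.ndim == x.ndim else idx.shape[0]
    idx_full = np.broadcast_to(idx, out_shape) if idx.ndim == x.ndim else None
    if idx_full is None:
        reshape = [1] * x.ndim
        reshape[axis] = -1
        idx_full = np.broadcast_to(idx.reshape(reshape), out_shape)
    out_data = np.take_along_axis(x.data, idx_full, axis=axis)

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        mesh = list(np.indices(out_data.shape, sparse=True))
        mesh[axis] = idx_full
        np.add.at(gx, tuple(mesh), g)
        x._accum(gx, own=True)

    return Tensor._make(out_data, (x,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from logits, numerically stable.

    loss_i = max(z,0) - z*y + log(1 + exp(-|z|)); gradient wrt z is
    sigmoid(z) - y, applied directly for stability.
    """
    logits = Tensor.as_tensor(logits)
    y = np.asarray(targets, dtype=np.float64)
    z = logits.data
    per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out_data = per.mean()

    def backward(g):
        if logits.requires_grad:
            p = 1.0 / (1.0 + np.exp(-z))
            logits._accum(g * (p - y) / y.size, own=True)

    return Tensor._make(out_data, (logits,), backward)
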