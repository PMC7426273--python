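"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  Only the operations needed by the models in this
package are implemented (elementwise arithmetic, matmul, reductions,
indexing, 2-d convolution / transposed convolution and a few pointwise
nonlinearities).  Gradients for broadcast operands are reduced back to the
operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "conv_transpose2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()
        self.name = name

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep graphs must not hit the recursion limit
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
        # interior-node grads are scratch space for this pass only; leaves
        # (parameters) keep accumulating across backward calls
        for node in topo:
            if node._parents:
                node.grad = None
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        if isinstance(p, Tensor):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    # -- pointwise --------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        return self**0.5

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, None, 500))),
            np.exp(np.clip(self.data, -500, None))
            / (1.0 + np.exp(np.clip(self.data, -500, None))),
        )

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def clamp(self, lo: float | None = None, hi: float | None = None):
        out_data = np.clip(self.data, lo, hi)
        inside = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            inside &= self.data >= lo
        if hi is not None:
            inside &= self.data <= hi

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * inside)

        return self._make(out_data, (self,), backward)

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.asarray(g).reshape(self.data.shape))

        return self._make(out_data, (self,), backward)

    @property
    def T(self):
        out_data = self.data.T

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.asarray(g).T)

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return self._make(out_data, (self,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        g = np.asarray(g)
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


# -- 2-d convolution ------------------------------------------------------

def _conv2d_forward(x: np.ndarray, w: np.ndarray, stride: int, padding: int):
    n, c, h, wd = x.shape
    o, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    oh = (h + 2 * padding - kh) // stride + 1
    ow = (wd + 2 * padding - kw) // stride + 1
    out = np.zeros((n, o, oh, ow))
    # loop over the (small) kernel footprint; each term is a strided slice
    for di in range(kh):
        for dj in range(kw):
            patch = xp[:, :, di : di + stride * oh : stride, dj : dj + stride * ow : stride]
            out += np.einsum("nchw,oc->nohw", patch, w[:, :, di, dj])
    return out, xp.shape


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of NCHW input `x` with OCKK kernel `w`."""
    x, w = _as_tensor(x), _as_tensor(w)
    out_data, xp_shape = _conv2d_forward(x.data, w.data, stride, padding)
    n, c, h, wd = x.data.shape
    o, _, kh, kw = w.data.shape
    oh, ow = out_data.shape[2], out_data.shape[3]

    def backward(g):
        g = np.asarray(g)
        if x.requires_grad:
            gx_p = np.zeros(xp_shape)
            for di in range(kh):
                for dj in range(kw):
                    gx_p[:, :, di : di + stride * oh : stride, dj : dj + stride * ow : stride] += np.einsum(
                        "nohw,oc->nchw", g, w.data[:, :, di, dj]
                    )
            gx = gx_p[:, :, padding : padding + h, padding : padding + wd]
            x._accumulate(gx)
        if w.requires_grad:
            xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
            gw = np.zeros_like(w.data)
            for di in range(kh):
                for dj in range(kw):
                    patch = xp[:, :, di : di + stride * oh : stride, dj : dj + stride * ow : stride]
                    gw[:, :, di, dj] = np.einsum("nohw,nchw->oc", g, patch)
            w._accumulate(gw)

    out = Tensor(out_data)
    parents = [x, w]
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    if b is not None:
        out = out + b.reshape(1, -1, 1, 1)
    return out


def conv_transpose2d(
    x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0
) -> Tensor:
    """Transposed convolution (the adjoint of :func:`conv2d`).

    `w` has shape (C_in, C_out, kh, kw); the output spatial size is
    ``(H - 1) * stride - 2 * padding + k``.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    n, ci, h, wd = x.data.shape
    _, co, kh, kw = w.data.shape
    oh = (h - 1) * stride - 2 * padding + kh
    ow = (wd - 1) * stride - 2 * padding + kw
    full = np.zeros((n, co, oh + 2 * padding, ow + 2 * padding))
    for di in range(kh):
        for dj in range(kw):
            full[:, :, di : di + stride * h : stride, dj : dj + stride * wd : stride] += np.einsum(
                "nihw,io->nohw", x.data, w.data[:, :, di, dj]
            )
    out_data = full[:, :, padding : padding + oh, padding : padding + ow]

    def backward(g):
        g = np.asarray(g)
        gp = np.pad(g, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for di in range(kh):
                for dj in range(kw):
                    patch = gp[:, :, di : di + stride * h : stride, dj : dj + stride * wd : stride]
                    gx += np.einsum("nohw,io->nihw", patch, w.data[:, :, di, dj])
            x._accumulate(gx)
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for di in range(kh):
                for dj in range(kw):
                    patch = gp[:, :, di : di + stride * h : stride, dj : dj + stride * wd : stride]
                    gw[:, :, di, dj] = np.einsum("nihw,nohw->io", x.data, patch)
            w._accumulate(gw)

    out = Tensor(out_data)
    parents = [x, w]
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    if b is not None:
        out = out + b.reshape(1, -1, 1, 1)
    return out
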