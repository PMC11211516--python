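"""Minimal reverse-mode automatic differentiation on numpy arrays.

The trainable parts of the package (graph attention encoders, the residual
image encoder and the fusion classifier) are small enough that a compact
vectorized autodiff core is sufficient: a :class:`Tensor` wraps an
``ndarray``, records its parents and a closure that propagates the adjoint,
and :meth:`Tensor.backward` runs the reverse sweep over a topological order.

Only the primitives the model needs are implemented (broadcasted arithmetic,
matmul, exp/log, rectifiers, reductions, indexing, concatenation and a
2-D convolution via im2col); everything else in the package is composed
from them.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an adjoint and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep residual graphs overflow recursion
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _accum(t: "Tensor", g: np.ndarray) -> None:
        if t.grad is None:
            t.grad = g.copy() if g.base is not None or True else g
        else:
            t.grad = t.grad + g

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                Tensor._accum(self, _unbroadcast(g, self.shape))
            if other.requires_grad:
                Tensor._accum(other, _unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            Tensor._accum(self, -g)

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
                Tensor._accum(self, _unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                Tensor._accum(other, _unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                Tensor._accum(self, _unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                Tensor._accum(
                    other,
                    _unbroadcast(-g * self.data / (other.data**2), other.shape),
                )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            Tensor._accum(self, g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b) if g.ndim else g * b
                elif a.ndim == 1:
                    ga = g @ b.swapaxes(-1, -2)
                else:
                    ga = g @ b.swapaxes(-1, -2)
                Tensor._accum(self, _unbroadcast(ga.reshape(a.shape) if ga.shape != a.shape and ga.size == a.size else ga, a.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g) if g.ndim else a * g
                elif b.ndim == 1:
                    gb = (a * g[..., None]).sum(axis=tuple(range(a.ndim - 1)))
                else:
                    gb = a.swapaxes(-1, -2) @ g
                Tensor._accum(other, _unbroadcast(gb, b.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            Tensor._accum(self, g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            Tensor._accum(self, g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            Tensor._accum(self, g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            Tensor._accum(self, g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        scale = np.where(mask, 1.0, slope)

        def backward(g):
            Tensor._accum(self, g * scale)

        return Tensor._make(self.data * scale, (self,), backward)

    def clip_min0(self):
        """min(x, 0) — the negative part, used to compose ELU/PReLU."""
        mask = self.data < 0

        def backward(g):
            Tensor._accum(self, g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def elu(self, alpha: float = 1.0):
        # x for x >= 0 ; alpha*(exp(x)-1) for x < 0, continuous at 0
        return self.relu() + alpha * (self.clip_min0().exp() - 1.0)

    def sqrt(self):
        return self**0.5

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward(g):
            Tensor._accum(self, g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            Tensor._accum(self, g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            Tensor._accum(self, full)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                Tensor._accum(self, np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.ndim for a in axes)
                shape = tuple(
                    1 if i in axes else s for i, s in enumerate(self.shape)
                )
                g = g.reshape(shape)
            Tensor._accum(self, np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a % self.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- stable softmax family -------------------------------------------------

    def log_softmax(self, axis: int = -1):
        shift = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shift - shift.exp().sum(axis=axis, keepdims=True).log()

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                Tensor._accum(t, g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def _im2col_indices(C, H, W, kh, kw, sh, sw, ph, pw):
    oh = (H + 2 * ph - kh) // sh + 1
    ow = (W + 2 * pw - kw) // sw + 1
    i0 = np.repeat(np.arange(kh), kw)
    i0 = np.tile(i0, C)
    i1 = sh * np.repeat(np.arange(oh), ow)
    j0 = np.tile(np.arange(kw), kh * C)
    j1 = sw * np.tile(np.arange(ow), oh)
    i = i0.reshape(-1, 1) + i1.reshape(1, -1)  # (C*kh*kw, oh*ow)
    j = j0.reshape(-1, 1) + j1.reshape(1, -1)
    k = np.repeat(np.arange(C), kh * kw).reshape(-1, 1)
    return k, i, j, oh, ow


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation. x: (N,C,H,W), w: (F,C,kh,kw), b: (F,) or None."""
    N, C, H, W = x.shape
    F, Cw, kh, kw = w.shape
    if C != Cw:
        raise ValueError(f"conv2d channel mismatch: input {C}, kernel {Cw}")
    k, i, j, oh, ow = _im2col_indices(C, H, W, kh, kw, stride, stride, padding, padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = xp[:, k, i, j]  # (N, C*kh*kw, oh*ow)
    wf = w.data.reshape(F, -1)
    out = np.einsum("fk,nkp->nfp", wf, cols).reshape(N, F, oh, ow)
    if b is not None:
        out = out + b.data.reshape(1, F, 1, 1)

    def backward(g):
        gf = g.reshape(N, F, oh * ow)
        if w.requires_grad:
            gw = np.einsum("nfp,nkp->fk", gf, cols).reshape(w.shape)
            Tensor._accum(w, gw)
        if b is not None and b.requires_grad:
            Tensor._accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.einsum("fk,nfp->nkp", wf, gf)
            gxp = np.zeros_like(xp)
            np.add.at(gxp, (slice(None), k, i, j), gcols)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            Tensor._accum(x, gxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)
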