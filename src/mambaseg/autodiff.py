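"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package's networks are small enough that a compact, correctness-first
tape suffices: every op records its parents and a closure that accumulates
vector-Jacobian products.  Dense convolutions are evaluated through
im2col/col2im so the heavy lifting stays inside BLAS; the selective-scan
recurrence has hand-written forward/backward kernels (see `ssm.py`) because
it is inherently sequential.

Only the operations the segmentation model needs are implemented.  All
floating tensors default to float32.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the context (inference / metrics)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_array(x, dtype=np.float32) -> np.ndarray:
    # float64 arrays are kept as-is so tests can run in double precision
    if isinstance(x, np.ndarray) and x.dtype in (np.float32, np.float64):
        return x
    return np.asarray(x, dtype=dtype)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _wrap(other, like: "Tensor") -> "Tensor":
    """Lift an operand to Tensor; scalar floats adopt `like`'s dtype so a
    float64 computation is never polluted by a float32 constant."""
    if isinstance(other, Tensor):
        return other
    arr = np.asarray(other)
    if arr.ndim == 0 and arr.dtype.kind in "fi":
        return Tensor(arr.astype(like.dtype))
    return Tensor(other)


class Tensor:
    """An ndarray plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")
    __array_priority__ = 100  # keep numpy from hijacking reflected ops

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._vjp: Callable[[np.ndarray], None] | None = None

    # -- construction ------------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              vjp: Callable[[np.ndarray], None]) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        # np.asarray keeps 0-d reduction results in their computed dtype
        out = Tensor(np.asarray(data), requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._vjp = vjp
        return out

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- properties --------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- backward pass -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
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
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._vjp is not None and node.grad is not None:
                node._vjp(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _wrap(other, self)
        a, b = self, other

        def vjp(g):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), vjp)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        other = _wrap(other, self)
        return self + (-other)

    def __rsub__(self, other):
        return _wrap(other, self) + (-self)

    def __mul__(self, other):
        other = _wrap(other, self)
        a, b = self, other

        def vjp(g):
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), vjp)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other, self)
        a, b = self, other
        out_data = a.data / b.data

        def vjp(g):
            a._accum(_unbroadcast(g / b.data, a.shape))
            b._accum(_unbroadcast(-g * out_data / b.data, b.shape))

        return Tensor._make(out_data, (a, b), vjp)

    def __rtruediv__(self, other):
        return _wrap(other, self) / self

    def __pow__(self, p: float):
        a = self
        return Tensor._make(
            a.data ** p, (a,),
            lambda g: a._accum(g * p * a.data ** (p - 1)))

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def vjp(g):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            a._accum(_unbroadcast(ga, a.shape))
            b._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), vjp)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: a._accum(g * out_data))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: a._accum(g / a.data))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._make(out_data, (a,), lambda g: a._accum(g * 0.5 / out_data))

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(s, (a,), lambda g: a._accum(g * s * (1.0 - s)))

    def silu(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(a.data * s, (a,),
                            lambda g: a._accum(g * s * (1.0 + a.data * (1.0 - s))))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(np.where(mask, a.data, 0.0), (a,),
                            lambda g: a._accum(g * mask))

    def softplus(self):
        # log(1 + e^x), computed stably; derivative is sigmoid(x)
        a = self
        out_data = np.logaddexp(0.0, a.data).astype(a.dtype)
        s = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(out_data, (a,), lambda g: a._accum(g * s))

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return Tensor._make(out_data, (a,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def amax(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.max(axis=axis, keepdims=True)
        mask = (a.data == out_data)
        # split gradient evenly across ties
        counts = mask.sum(axis=axis, keepdims=True)
        res = out_data if keepdims or axis is None else np.squeeze(out_data, axis=axis)

        def vjp(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape) * mask / counts)

        return Tensor._make(res if axis is not None or keepdims else out_data.reshape(()),
                            (a,), vjp)

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor._make(a.data.reshape(shape), (a,),
                            lambda g: a._accum(g.reshape(a.shape)))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        return Tensor._make(a.data.transpose(axes), (a,),
                            lambda g: a._accum(g.transpose(inv)))

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]

        def vjp(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._make(out_data, (a,), vjp)

    def take_tokens(self, idx: np.ndarray):
        """Permute axis 1 by an index permutation (scan reorderings).

        `idx` must be a permutation of arange(L); the backward pass uses the
        inverse permutation, so no scatter-add is needed.
        """
        a = self
        inv = np.empty_like(idx)
        inv[idx] = np.arange(idx.size)
        return Tensor._make(np.ascontiguousarray(a.data[:, idx]), (a,),
                            lambda g: a._accum(g[:, inv]))


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, vjp)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    return concat([t.reshape(t.shape[:axis] + (1,) + t.shape[axis:]) for t in tensors],
                  axis=axis)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; the row-max shift is treated as constant."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


# -- spatial primitives ----------------------------------------------------

def _conv_out_size(n: int, k: int, stride: int, pad: int, dil: int) -> int:
    return (n + 2 * pad - dil * (k - 1) - 1) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int, dil: int):
    B, C, H, W = x.shape
    OH = _conv_out_size(H, kh, stride, pad, dil)
    OW = _conv_out_size(W, kw, stride, pad, dil)
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((B, C, kh, kw, OH, OW), dtype=x.dtype)
    for i in range(kh):
        hi = i * dil
        for j in range(kw):
            wj = j * dil
            cols[:, :, i, j] = x[:, :, hi:hi + OH * stride:stride,
                                 wj:wj + OW * stride:stride]
    return cols, OH, OW


def _col2im(cols: np.ndarray, x_shape, kh, kw, stride, pad, dil):
    B, C, H, W = x_shape
    OH, OW = cols.shape[-2:]
    xp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        hi = i * dil
        for j in range(kw):
            wj = j * dil
            xp[:, :, hi:hi + OH * stride:stride, wj:wj + OW * stride:stride] += \
                cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1,
           groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (Cout, Cin/groups, kh, kw)."""
    B, C, H, W = x.shape
    Cout, Cg, kh, kw = weight.shape
    if C != Cg * groups or Cout % groups:
        raise ValueError(f"conv2d channel mismatch: x has {C}, weight {weight.shape}, "
                         f"groups {groups}")
    cols, OH, OW = _im2col(x.data, kh, kw, stride, padding, dilation)
    # (B, g, Cg*kh*kw, OH*OW)
    colm = cols.reshape(B, groups, Cg * kh * kw, OH * OW)
    wm = weight.data.reshape(groups, Cout // groups, Cg * kh * kw)
    out = np.einsum("gok,bgkl->bgol", wm, colm, optimize=True)
    out = out.reshape(B, Cout, OH, OW)
    if bias is not None:
        out = out + bias.data.reshape(1, Cout, 1, 1)
    parents = [x, weight] + ([bias] if bias is not None else [])

    def vjp(g):
        gm = g.reshape(B, groups, Cout // groups, OH * OW)
        if weight.requires_grad:
            gw = np.einsum("bgol,bgkl->gok", gm, colm, optimize=True)
            weight._accum(gw.reshape(weight.shape))
        if x.requires_grad:
            gcols = np.einsum("gok,bgol->bgkl", wm, gm, optimize=True)
            gcols = gcols.reshape(B, C, kh, kw, OH, OW)
            x._accum(_col2im(gcols, x.shape, kh, kw, stride, padding, dilation))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, parents, vjp)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
                     stride: int = 2) -> Tensor:
    """Transposed convolution with kernel == stride (exact s× upsampling).

    weight layout (Cin, Cout, k, k); each input pixel paints a disjoint
    k×k output tile, so forward and backward are plain strided assignments.
    """
    B, Cin, H, W = x.shape
    Cin_w, Cout, kh, kw = weight.shape
    if Cin != Cin_w or kh != stride or kw != stride:
        raise ValueError("conv_transpose2d requires kernel == stride and matching Cin")
    out = np.empty((B, Cout, H * stride, W * stride), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            # (B,H,W,Cin) @ (Cin,Cout) -> (B,H,W,Cout)
            t = np.einsum("bchw,co->bohw", x.data, weight.data[:, :, i, j],
                          optimize=True)
            out[:, :, i::stride, j::stride] = t
    if bias is not None:
        out = out + bias.data.reshape(1, Cout, 1, 1)
    parents = [x, weight] + ([bias] if bias is not None else [])

    def vjp(g):
        gx = np.zeros_like(x.data) if x.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                gij = g[:, :, i::stride, j::stride]
                if weight.requires_grad:
                    gw = np.einsum("bchw,bohw->co", x.data, gij, optimize=True)
                    if weight.grad is None:
                        weight.grad = np.zeros_like(weight.data)
                    weight.grad[:, :, i, j] += gw
                if gx is not None:
                    gx += np.einsum("bohw,co->bchw", gij, weight.data[:, :, i, j],
                                    optimize=True)
        if gx is not None:
            x._accum(gx)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, parents, vjp)


def upsample_bilinear(x: Tensor, scale: int) -> Tensor:
    """Bilinear upsampling by an integer factor (half-pixel centers)."""
    B, C, H, W = x.shape
    OH, OW = H * scale, W * scale

    def _axis_weights(n_in, n_out):
        # output center i maps to input coordinate (i + 0.5)/scale - 0.5
        coords = (np.arange(n_out) + 0.5) / scale - 0.5
        lo = np.floor(coords).astype(np.int64)
        frac = (coords - lo).astype(np.float32)
        lo = np.clip(lo, 0, n_in - 1)
        hi = np.clip(lo + 1, 0, n_in - 1)
        return lo, hi, frac

    ylo, yhi, fy = _axis_weights(H, OH)
    xlo, xhi, fx = _axis_weights(W, OW)
    fy = fy.reshape(1, 1, OH, 1)
    fx = fx.reshape(1, 1, 1, OW)

    d = x.data
    top = d[:, :, ylo][:, :, :, xlo] * (1 - fx) + d[:, :, ylo][:, :, :, xhi] * fx
    bot = d[:, :, yhi][:, :, :, xlo] * (1 - fx) + d[:, :, yhi][:, :, :, xhi] * fx
    out = top * (1 - fy) + bot * fy

    def vjp(g):
        gx = np.zeros_like(d)
        for rows, grow in ((ylo, g * (1 - fy)), (yhi, g * fy)):
            np.add.at(gx, (slice(None), slice(None), rows[:, None], xlo[None, :]),
                      grow * (1 - fx))
            np.add.at(gx, (slice(None), slice(None), rows[:, None], xhi[None, :]),
                      grow * fx)
        x._accum(gx)

    return Tensor._make(out.astype(d.dtype), (x,), vjp)
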