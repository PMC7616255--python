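"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is deliberately small: a :class:`Tensor` wraps an ``ndarray`` and
remembers, for every operation, its parents and one vector-Jacobian-product
(vjp) closure per parent.  The vjp closures are themselves written in terms of
engine operations, so calling :func:`grad` with ``create_graph=True`` produces
gradients that are again differentiable.  That second-order capability is what
lets the WGAN gradient penalty — a loss built from the norm of an input
gradient — be optimised with respect to the critic's weights.

Only the operations needed by 3D convolutional encoder/decoder networks are
provided: elementwise arithmetic, matmul, reductions, shape ops, leaky
rectification, sigmoid, strided 3D convolution (with its two adjoint kernels)
and nearest-neighbour upsampling.  Everything is float numpy under the hood;
there is no device abstraction.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "pow_const",
    "exp",
    "log",
    "sqrt",
    "matmul",
    "tsum",
    "tmean",
    "reshape",
    "transpose",
    "broadcast_to",
    "sum_to",
    "leaky_relu",
    "sigmoid",
    "conv3d",
    "im2col",
    "col2im",
    "upsample_nearest",
    "downsample_sum",
    "grad",
]

_GRAD_ENABLED = True


class no_grad(contextlib.AbstractContextManager):
    """Context manager that disables graph construction."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    __slots__ = ("data", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind in "iub":
            arr = arr.astype(np.float64)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._vjps: tuple[Callable[[Tensor], Tensor], ...] = ()

    # -- inspection ------------------------------------------------------
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

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return pow_const(self, p)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def scalar(v: float) -> Tensor:
    """A 0-d float32 constant; elementwise ops weaken it to the other
    operand's dtype, so float32 graphs stay float32 and float64 stay float64."""
    return Tensor(np.asarray(v, dtype=np.float32))


def _make(data: np.ndarray, parents: Sequence[Tensor], vjps: Sequence[Callable]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._vjps = tuple(vjps)
    return out


# -- broadcasting helpers ------------------------------------------------

def sum_to(t: Tensor, shape: tuple) -> Tensor:
    """Sum ``t`` down to ``shape`` (the adjoint of numpy broadcasting)."""
    t = as_tensor(t)
    if t.shape == tuple(shape):
        return t
    ndim_extra = t.ndim - len(shape)
    axes = tuple(range(ndim_extra))
    axes += tuple(
        i + ndim_extra for i, s in enumerate(shape) if s == 1 and t.shape[i + ndim_extra] != 1
    )
    out = tsum(t, axis=axes, keepdims=True) if axes else t
    return reshape(out, tuple(shape))


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    if a.shape == shape:
        return a
    data = np.broadcast_to(a.data, shape)
    return _make(np.ascontiguousarray(data), [a], [lambda g, sh=a.shape: sum_to(g, sh)])


# -- elementwise arithmetic ----------------------------------------------

def _pair(a: Tensor, b: Tensor) -> tuple[np.ndarray, np.ndarray]:
    """Operand data with 0-d scalars weakened to the array operand's dtype
    (mirrors python-scalar promotion; keeps float32 graphs in float32)."""
    x, y = a.data, b.data
    if x.ndim == 0 and y.ndim > 0 and x.dtype != y.dtype:
        x = x.astype(y.dtype)
    elif y.ndim == 0 and x.ndim > 0 and y.dtype != x.dtype:
        y = y.astype(x.dtype)
    return x, y


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    x, y = _pair(a, b)
    return _make(
        x + y,
        [a, b],
        [lambda g, sh=a.shape: sum_to(g, sh), lambda g, sh=b.shape: sum_to(g, sh)],
    )


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    x, y = _pair(a, b)
    return _make(
        x - y,
        [a, b],
        [lambda g, sh=a.shape: sum_to(g, sh), lambda g, sh=b.shape: sum_to(neg(g), sh)],
    )


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    x, y = _pair(a, b)
    return _make(
        x * y,
        [a, b],
        [
            lambda g, o=b, sh=a.shape: sum_to(mul(g, o), sh),
            lambda g, o=a, sh=b.shape: sum_to(mul(g, o), sh),
        ],
    )


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    x, y = _pair(a, b)
    return _make(
        x / y,
        [a, b],
        [
            lambda g, o=b, sh=a.shape: sum_to(div(g, o), sh),
            lambda g, x=a, y=b, sh=b.shape: sum_to(neg(div(mul(g, x), mul(y, y))), sh),
        ],
    )


def neg(a) -> Tensor:
    a = as_tensor(a)
    return _make(-a.data, [a], [lambda g: neg(g)])


def pow_const(a, p: float) -> Tensor:
    a = as_tensor(a)
    p = float(p)
    return _make(
        a.data**p,
        [a],
        [lambda g, x=a: mul(g, mul(scalar(p), pow_const(x, p - 1.0)))],
    )


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)
    out = _make(out_data, [a], [])
    if out.requires_grad:
        out._vjps = (lambda g, o=out: mul(g, o),)
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.log(a.data), [a], [lambda g, x=a: div(g, x)])


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.sqrt(a.data)
    out = _make(out_data, [a], [])
    if out.requires_grad:
        out._vjps = (lambda g, o=out: div(mul(g, scalar(0.5)), o),)
    return out


# -- linear algebra and reductions ---------------------------------------

def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError(f"matmul expects 2D operands, got {a.shape} @ {b.shape}")
    return _make(
        a.data @ b.data,
        [a, b],
        [
            lambda g, o=b: matmul(g, transpose(o, (1, 0))),
            lambda g, o=a: matmul(transpose(o, (1, 0)), g),
        ],
    )


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis % a.ndim,)
    else:
        axes = tuple(ax % a.ndim for ax in axis)
    data = a.data.sum(axis=axes, keepdims=keepdims)

    def vjp(g, in_shape=a.shape, axes=axes, keepdims=keepdims):
        if not keepdims:
            kd_shape = tuple(1 if i in axes else s for i, s in enumerate(in_shape))
            g = reshape(g, kd_shape)
        return broadcast_to(g, in_shape)

    return _make(data, [a], [vjp])


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.size
    elif isinstance(axis, int):
        n = a.shape[axis % a.ndim]
    else:
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axis]))
    factor = Tensor(np.asarray(1.0 / n, dtype=a.data.dtype))  # full operand precision
    return mul(tsum(a, axis=axis, keepdims=keepdims), factor)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    return _make(
        a.data.reshape(shape), [a], [lambda g, sh=a.shape: reshape(g, sh)]
    )


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _make(
        np.ascontiguousarray(a.data.transpose(axes)),
        [a],
        [lambda g: transpose(g, inv)],
    )


# -- nonlinearities -------------------------------------------------------

def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    factor = np.where(a.data > 0, 1.0, slope).astype(a.data.dtype)
    # the derivative mask is piecewise constant; treated as a constant in the
    # graph, so double backprop through the critic is exact almost everywhere
    return _make(a.data * factor, [a], [lambda g, f=Tensor(factor): mul(g, f)])


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))
    out = _make(out_data, [a], [])
    if out.requires_grad:
        out._vjps = (lambda g, o=out: mul(g, mul(o, sub(scalar(1.0), o))),)
    return out


# -- 3D convolution -------------------------------------------------------
#
# Volumes flow through convolutions in CNDHW layout (channels first, batch
# second).  With that layout the patch matrix has shape (C·k³, N·P) and every
# product in forward and backward is one large GEMM with no transposed
# copies, which is what keeps CPU training affordable.
#
# conv3d is composed from two primitives so the expensive patch matrix is a
# shared graph node: ``im2col`` (a linear gather whose adjoint is the
# scatter-add ``col2im``) and ``colmm``, the channel contraction
# out[o,np] = sum_ck w[o,ck] col[ck,np].  colmm and its two partial adjoints
# realise the trilinear form T(w, col, g) = <colmm(w, col), g>, so the vjp
# of any of them is again one of the three — the closure property that makes
# the gradient penalty twice differentiable.


def _conv_out_side(d: int, k: int, stride: int, pad: int) -> int:
    return (d + 2 * pad - k) // stride + 1


def _im2col_raw(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    c, n, d, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    do = _conv_out_side(d, k, stride, pad)
    ho = _conv_out_side(h, k, stride, pad)
    wo = _conv_out_side(wd, k, stride, pad)
    col = np.empty((c, k, k, k, n, do, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                col[:, i, j, l] = xp[
                    :,
                    :,
                    i : i + stride * do : stride,
                    j : j + stride * ho : stride,
                    l : l + stride * wo : stride,
                ]
    return col.reshape(c * k**3, n * do * ho * wo)


def _col2im_raw(
    gcol: np.ndarray, in_shape: tuple, k: int, stride: int, pad: int
) -> np.ndarray:
    c, n, d, h, wd = in_shape
    do = _conv_out_side(d, k, stride, pad)
    ho = _conv_out_side(h, k, stride, pad)
    wo = _conv_out_side(wd, k, stride, pad)
    g = gcol.reshape(c, k, k, k, n, do, ho, wo)
    xp = np.zeros((c, n, d + 2 * pad, h + 2 * pad, wd + 2 * pad), dtype=gcol.dtype)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                xp[
                    :,
                    :,
                    i : i + stride * do : stride,
                    j : j + stride * ho : stride,
                    l : l + stride * wo : stride,
                ] += g[:, i, j, l]
    if pad == 0:
        return xp
    return np.ascontiguousarray(xp[:, :, pad:-pad, pad:-pad, pad:-pad])


def im2col(x, k: int, stride: int, pad: int) -> Tensor:
    x = as_tensor(x)
    in_shape = x.shape
    return _make(
        _im2col_raw(x.data, k, stride, pad),
        [x],
        [lambda g: col2im(g, in_shape, k, stride, pad)],
    )


def col2im(gcol, in_shape: tuple, k: int, stride: int, pad: int) -> Tensor:
    gcol = as_tensor(gcol)
    return _make(
        _col2im_raw(gcol.data, tuple(in_shape), k, stride, pad),
        [gcol],
        [lambda g: im2col(g, k, stride, pad)],
    )


def colmm(w2, col) -> Tensor:
    """out[o,np] = sum_ck w2[o,ck] · col[ck,np]."""
    w2, col = as_tensor(w2), as_tensor(col)
    return _make(
        w2.data @ col.data,
        [w2, col],
        [
            lambda g, c=col: colmm_wgrad(g, c),
            lambda g, w=w2: colmm_colgrad(w, g),
        ],
    )


def colmm_wgrad(g, col) -> Tensor:
    """dT/dw2[o,ck] = sum_np g[o,np] · col[ck,np]."""
    g, col = as_tensor(g), as_tensor(col)
    return _make(
        g.data @ col.data.T,
        [g, col],
        [
            lambda u, c=col: colmm(u, c),
            lambda u, gt=g: colmm_colgrad(u, gt),
        ],
    )


def colmm_colgrad(w2, g) -> Tensor:
    """dT/dcol[ck,np] = sum_o w2[o,ck] · g[o,np]."""
    w2, g = as_tensor(w2), as_tensor(g)
    return _make(
        w2.data.T @ g.data,
        [w2, g],
        [
            lambda u, gt=g: colmm_wgrad(gt, u),
            lambda u, w=w2: colmm(w, u),
        ],
    )


def conv3d(x, w, stride: int = 1, pad: int = 1) -> Tensor:
    """3D cross-correlation, CNDHW input, (O, C, k, k, k) kernel."""
    x, w = as_tensor(x), as_tensor(w)
    o, c, k = w.shape[0], w.shape[1], w.shape[-1]
    if x.ndim != 5 or x.shape[0] != c:
        raise ValueError(f"conv3d input {x.shape} incompatible with kernel {w.shape}")
    _, n, d, h, wd = x.shape
    do = _conv_out_side(d, k, stride, pad)
    ho = _conv_out_side(h, k, stride, pad)
    wo = _conv_out_side(wd, k, stride, pad)
    col = im2col(x, k, stride, pad)
    w2 = reshape(w, (o, c * k**3))
    out = colmm(w2, col)
    return reshape(out, (o, n, do, ho, wo))


# -- resampling -----------------------------------------------------------

def upsample_nearest(x, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of an NCDHW tensor by an integer factor."""
    x = as_tensor(x)
    f = int(factor)
    data = x.data.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4)
    return _make(data, [x], [lambda g: downsample_sum(g, f)])


def downsample_sum(x, factor: int = 2) -> Tensor:
    """Sum-pool an NCDHW tensor over non-overlapping ``factor``³ blocks."""
    x = as_tensor(x)
    f = int(factor)
    n, c, d, h, w = x.shape
    data = x.data.reshape(n, c, d // f, f, h // f, f, w // f, f).sum(axis=(3, 5, 7))
    return _make(data, [x], [lambda g: upsample_nearest(g, f)])


# -- backward pass --------------------------------------------------------

def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen and p.requires_grad:
                stack.append((p, False))
    return order


def grad(
    output: Tensor,
    inputs: Sequence[Tensor],
    cotangent=None,
    create_graph: bool = False,
) -> list[Tensor]:
    """Gradients of a scalar ``output`` with respect to ``inputs``.

    With ``create_graph=True`` the returned gradients carry their own graph,
    so expressions of them (e.g. a gradient-norm penalty) remain
    differentiable.
    """
    if not output.requires_grad:
        raise ValueError("output does not require grad; nothing to differentiate")
    if cotangent is None:
        cot0 = Tensor(np.ones_like(output.data))
    else:
        cot0 = as_tensor(cotangent)

    ctx = contextlib.nullcontext() if create_graph else no_grad()
    cot: dict[int, Tensor] = {id(output): cot0}
    with ctx:
        for node in reversed(_toposort(output)):
            g = cot.pop(id(node), None)
            if g is None:
                continue
            for parent, vjp in zip(node._parents, node._vjps):
                if not parent.requires_grad:
                    continue
                pg = vjp(g)
                prev = cot.get(id(parent))
                cot[id(parent)] = pg if prev is None else add(prev, pg)
            # keep the input gradients even though inputs may appear mid-graph
            for inp in inputs:
                if id(inp) == id(node) and g is not None:
                    cot[id(node)] = g
    out = []
    for inp in inputs:
        gi = cot.get(id(inp))
        if gi is None:
            gi = Tensor(np.zeros_like(inp.data))
        out.append(gi)
    return out
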