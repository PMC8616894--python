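"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module exists because the package trains small convolutional networks
(generator, discriminator, auxiliary classifier) and no deep-learning
framework is assumed to be installed.  It provides a :class:`Tensor` wrapping
a numpy array, a set of differentiable primitives, and composite operations
(convolution via im2col, instance statistics, stable softplus/sigmoid).

Design constraints:

* Every primitive's vector-Jacobian product (VJP) is itself expressed in
  Tensor operations, so gradients are differentiable: ``grad(...,
  create_graph=True)`` supports the double backpropagation required by the
  R1 gradient penalty (the gradient of a gradient-norm penalty with respect
  to network parameters).
* Dtypes are preserved: float32 throughout the networks for speed, float64
  when callers pass float64 (metric-grade accuracy in tests).
* No global mutable state beyond a grad-enabled flag (``no_grad``).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "grad",
    "add",
    "mul",
    "matmul",
    "tsum",
    "mean",
    "reshape",
    "swapaxes",
    "broadcast_to",
    "concat",
    "getitem",
    "pad2d",
    "im2col",
    "col2im",
    "conv2d",
    "exp",
    "log",
    "sqrt",
    "tanh",
    "sigmoid",
    "softplus",
    "power",
    "relu",
    "leaky_relu",
    "maximum_const",
    "upsample2_nearest",
    "avg_pool2",
]

_GRAD_STACK = [True]


def _grad_enabled() -> bool:
    return _GRAD_STACK[-1]


class no_grad:
    """Context manager disabling graph recording (forward-only evaluation)."""

    def __enter__(self):
        _GRAD_STACK.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_STACK.pop()
        return False


class Tensor:
    """A numpy array with an optional autodiff graph node attached."""

    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self.grad: "Tensor | None" = None
        self._parents: tuple = ()
        self._vjp = None

    # ---- basic protocol -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        flag = ", requires_grad=True" if self.requires_grad else ""
        return f"Tensor({self.data!r}{flag})"

    # ---- operators ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, c):
        return power(self, c)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    # ---- backward -------------------------------------------------------
    def backward(self, gradient: "Tensor | np.ndarray | None" = None,
                 create_graph: bool = False) -> None:
        """Accumulate gradients of ``self`` into the ``.grad`` of leaves."""
        if gradient is None:
            if self.data.size != 1:
                raise ValueError("backward() on non-scalar requires an explicit gradient")
            gradient = Tensor(np.ones_like(self.data))
        gradient = as_tensor(gradient)
        gmap = _backprop(self, gradient, create_graph)
        for node, g in gmap.items():
            t = node
            if t.requires_grad and t._vjp is None:  # leaf
                t.grad = g if t.grad is None else add(t.grad, g)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], vjp) -> Tensor:
    out = Tensor(data)
    if _grad_enabled() and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._vjp = vjp
    return out


def _backprop(output: Tensor, seed: Tensor, create_graph: bool):
    """Return {tensor: grad Tensor} for all graph nodes reachable from output."""
    topo: list[Tensor] = []
    visited: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in visited:
                stack.append((p, False))

    grads: dict[Tensor, Tensor] = {}
    gmap: dict[int, Tensor] = {id(output): seed}
    keep: dict[int, Tensor] = {id(output): output}
    for node in reversed(topo):
        g = gmap.get(id(node))
        if g is None:
            continue
        grads[node] = g
        if node._vjp is None:
            continue
        if create_graph:
            parent_grads = node._vjp(g)
        else:
            with no_grad():
                parent_grads = node._vjp(g)
        for p, pg in zip(node._parents, parent_grads):
            if pg is None or not p.requires_grad:
                continue
            if id(p) in gmap:
                if create_graph:
                    gmap[id(p)] = add(gmap[id(p)], pg)
                else:
                    with no_grad():
                        gmap[id(p)] = add(gmap[id(p)], pg)
            else:
                gmap[id(p)] = pg
                keep[id(p)] = p
    return grads


def grad(output: Tensor, inputs: Iterable[Tensor],
         create_graph: bool = False) -> list[Tensor]:
    """Gradients of a scalar ``output`` w.r.t. ``inputs`` (functional API).

    With ``create_graph=True`` the returned tensors carry their own graph, so
    expressions built from them (e.g. a gradient-norm penalty) can be
    backpropagated again.
    """
    inputs = list(inputs)
    if output.data.size != 1:
        raise ValueError("grad() expects a scalar output")
    seed = Tensor(np.ones_like(output.data))
    gmap = _backprop(output, seed, create_graph)
    out = []
    for t in inputs:
        g = gmap.get(t)
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        out.append(g)
    return out


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce ``g`` back to ``shape`` after numpy broadcasting."""
    while g.data.ndim > len(shape):
        g = tsum(g, axis=0)
    axes = tuple(i for i, (gd, sd) in enumerate(zip(g.data.shape, shape))
                 if sd == 1 and gd != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


def _match_scalar_dtype(a: Tensor, b: Tensor) -> tuple[Tensor, Tensor]:
    """Keep float32 graphs float32 when mixed with 0-d float64 constants."""
    if (a.data.ndim == 0 and not a.requires_grad
            and b.data.dtype == np.float32 and a.data.dtype != np.float32):
        a = Tensor(a.data.astype(np.float32))
    elif (b.data.ndim == 0 and not b.requires_grad
            and a.data.dtype == np.float32 and b.data.dtype != np.float32):
        b = Tensor(b.data.astype(np.float32))
    return a, b


def add(a, b) -> Tensor:
    a, b = _match_scalar_dtype(as_tensor(a), as_tensor(b))

    def vjp(g):
        return (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), vjp)


def mul(a, b) -> Tensor:
    a, b = _match_scalar_dtype(as_tensor(a), as_tensor(b))

    def vjp(g):
        return (_unbroadcast(mul(g, b), a.data.shape),
                _unbroadcast(mul(g, a), b.data.shape))

    return _make(a.data * b.data, (a, b), vjp)


def power(a, c: float) -> Tensor:
    a = as_tensor(a)
    c = float(c)

    def vjp(g):
        return (mul(g, mul(power(a, c - 1.0), c)),)

    return _make(a.data ** c, (a,), vjp)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        ga = _unbroadcast(matmul(g, swapaxes(b, -1, -2)), a.data.shape)
        gb = _unbroadcast(matmul(swapaxes(a, -1, -2), g), b.data.shape)
        return (ga, gb)

    return _make(a.data @ b.data, (a, b), vjp)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    in_shape = a.data.shape

    def vjp(g):
        gg = g
        if axis is None:
            if not keepdims:
                gg = reshape(gg, (1,) * len(in_shape))
        elif not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % len(in_shape) for ax in axes)
            shape = tuple(1 if i in axes else s for i, s in enumerate(in_shape))
            gg = reshape(gg, shape)
        return (broadcast_to(gg, in_shape),)

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), vjp)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = 1
        for ax in axes:
            n *= a.data.shape[ax]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    in_shape = a.data.shape

    def vjp(g):
        return (_unbroadcast(g, in_shape),)

    return _make(np.broadcast_to(a.data, shape), (a,), vjp)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    in_shape = a.data.shape

    def vjp(g):
        return (reshape(g, in_shape),)

    return _make(a.data.reshape(shape), (a,), vjp)


def swapaxes(a, i: int, j: int) -> Tensor:
    a = as_tensor(a)

    def vjp(g):
        return (swapaxes(g, i, j),)

    return _make(np.swapaxes(a.data, i, j), (a,), vjp)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        outs = []
        for k in range(len(tensors)):
            key = [slice(None)] * g.data.ndim
            key[axis] = slice(int(offsets[k]), int(offsets[k + 1]))
            outs.append(getitem(g, tuple(key)))
        return tuple(outs)

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tensors, vjp)


def getitem(a, key) -> Tensor:
    a = as_tensor(a)
    in_shape = a.data.shape

    def vjp(g):
        return (_scatter(g, in_shape, key),)

    return _make(a.data[key], (a,), vjp)


def _scatter(g, shape, key) -> Tensor:
    """Adjoint of basic (non-repeating) indexing: place ``g`` at ``key``."""
    g = as_tensor(g)

    def vjp(gg):
        return (getitem(gg, key),)

    buf = np.zeros(shape, dtype=g.data.dtype)
    buf[key] = g.data
    return _make(buf, (g,), vjp)


def pad2d(a, p: int) -> Tensor:
    """Zero-pad the last two axes by ``p`` on each side."""
    a = as_tensor(a)
    if p == 0:
        return a

    def vjp(g):
        key = (Ellipsis, slice(p, -p), slice(p, -p))
        return (getitem(g, key),)

    width = [(0, 0)] * (a.data.ndim - 2) + [(p, p), (p, p)]
    return _make(np.pad(a.data, width), (a,), vjp)


def im2col(x, kh: int, kw: int, stride: int = 1) -> Tensor:
    """(B, C, H, W) -> (B, C, kh*kw, OH*OW) patch matrix (input pre-padded)."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    oh = (H - kh) // stride + 1
    ow = (W - kw) // stride + 1

    def vjp(g):
        return (col2im(g, H, W, kh, kw, stride),)

    cols = np.empty((B, C, kh * kw, oh * ow), dtype=x.data.dtype)
    k = 0
    for dy in range(kh):
        for dx in range(kw):
            cols[:, :, k, :] = x.data[:, :, dy:dy + stride * oh:stride,
                                      dx:dx + stride * ow:stride].reshape(B, C, -1)
            k += 1
    return _make(cols, (x,), vjp)


def col2im(cols, H: int, W: int, kh: int, kw: int, stride: int = 1) -> Tensor:
    """Adjoint of :func:`im2col`: overlap-add patches back onto the image."""
    cols = as_tensor(cols)
    B, C, K, L = cols.data.shape
    oh = (H - kh) // stride + 1
    ow = (W - kw) // stride + 1

    def vjp(g):
        return (im2col(g, kh, kw, stride),)

    buf = np.zeros((B, C, H, W), dtype=cols.data.dtype)
    k = 0
    for dy in range(kh):
        for dx in range(kw):
            buf[:, :, dy:dy + stride * oh:stride, dx:dx + stride * ow:stride] += \
                cols.data[:, :, k, :].reshape(B, C, oh, ow)
            k += 1
    return _make(buf, (cols,), vjp)


# --------------------------------------------------------------------------
# elementwise nonlinearities (VJPs reference the stored output tensor)
# --------------------------------------------------------------------------

def _unary(a, fn, vjp_builder) -> Tensor:
    a = as_tensor(a)
    out = _make(fn(a.data), (a,), None)
    if out._parents or (_grad_enabled() and a.requires_grad):
        out._parents = (a,)
        out._vjp = vjp_builder(a, out)
        out.requires_grad = True
    return out


def exp(a) -> Tensor:
    return _unary(a, np.exp, lambda a, out: lambda g: (mul(g, out),))


def log(a) -> Tensor:
    return _unary(a, np.log, lambda a, out: lambda g: (mul(g, power(a, -1.0)),))


def sqrt(a) -> Tensor:
    return _unary(a, np.sqrt,
                  lambda a, out: lambda g: (mul(g, mul(power(out, -1.0), 0.5)),))


def tanh(a) -> Tensor:
    return _unary(a, np.tanh,
                  lambda a, out: lambda g: (mul(g, add(1.0, mul(mul(out, out), -1.0))),))


def sigmoid(a) -> Tensor:
    def fn(x):
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out

    return _unary(a, fn,
                  lambda a, out: lambda g: (mul(g, mul(out, add(1.0, mul(out, -1.0)))),))


def softplus(a) -> Tensor:
    """Numerically stable log(1 + exp(a)) = relu(a) + log1p(exp(-|a|))."""
    a = as_tensor(a)
    m = Tensor((a.data > 0).astype(a.data.dtype))
    sign = mul(m, 2.0) - 1.0          # +1 where a>0, -1 elsewhere (constant)
    absa = mul(a, sign)
    return add(mul(a, m), log(add(exp(mul(absa, -1.0)), 1.0)))


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = Tensor((a.data > 0).astype(a.data.dtype))
    return mul(a, mask)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    scale = np.where(a.data > 0, 1.0, slope).astype(a.data.dtype)
    return mul(a, Tensor(scale))


def maximum_const(a, c: float) -> Tensor:
    """max(a, c) with a treated piecewise (subgradient at the kink)."""
    a = as_tensor(a)
    mask = (a.data > c).astype(a.data.dtype)
    return add(mul(a, Tensor(mask)), Tensor((1.0 - mask) * c))


# --------------------------------------------------------------------------
# composite spatial operations
# --------------------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) for NCHW input, OIHW weights."""
    x, w = as_tensor(x), as_tensor(w)
    B, C, H, W = x.data.shape
    OC, IC, kh, kw = w.data.shape
    if IC != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {IC}")
    xp = pad2d(x, padding)
    oh = (H + 2 * padding - kh) // stride + 1
    ow = (W + 2 * padding - kw) // stride + 1
    cols = reshape(im2col(xp, kh, kw, stride), (B, C * kh * kw, oh * ow))
    w2 = reshape(w, (1, OC, C * kh * kw))
    out = reshape(matmul(w2, cols), (B, OC, oh, ow))
    if b is not None:
        out = add(out, reshape(as_tensor(b), (1, OC, 1, 1)))
    return out


def upsample2_nearest(x) -> Tensor:
    """Nearest-neighbour 2x upsampling of NCHW input."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    x6 = reshape(x, (B, C, H, 1, W, 1))
    ones = Tensor(np.ones((1, 1, 1, 2, 1, 2), dtype=x.data.dtype))
    return reshape(mul(x6, ones), (B, C, 2 * H, 2 * W))


def spatial_max(x) -> Tensor:
    """Per-sample, per-channel max over the spatial axes of NCHW input.

    Realized as a gather at the (constant) argmax indices, so the gradient
    routes to the maximizing pixel (standard max-pool subgradient).
    """
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    flat_idx = x.data.reshape(B, C, -1).argmax(axis=2)
    bi, ci = np.meshgrid(np.arange(B), np.arange(C), indexing="ij")
    key = (bi, ci, flat_idx // W, flat_idx % W)
    return getitem(x, key)


def avg_pool2(x) -> Tensor:
    """2x2 average pooling; trailing odd row/column is dropped."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        x = getitem(x, (Ellipsis, slice(0, H - H % 2), slice(0, W - W % 2)))
        H, W = H - H % 2, W - W % 2
    x6 = reshape(x, (B, C, H // 2, 2, W // 2, 2))
    return mean(x6, axis=(3, 5))
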