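"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine provides exactly the operator set the windowed-attention network
and its composite objective need: broadcasting arithmetic, batched matmul,
shape manipulation, softmax / layer-norm / GELU fused primitives, 2-D
convolutions (dense, depth-wise, and 2x2 stride-2 transposed) and average
pooling.  Tensors hold float32 data by default; gradients are accumulated in
the same dtype.

Graphs are built eagerly.  ``Tensor.backward()`` runs a topological sweep.
Wrap inference code in ``no_grad()`` to skip graph construction.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference / metrics)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, dtype=np.float32):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=dtype)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ---------------------------------------------------------------- basics
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

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate state eagerly; leaves keep their grads
                node._backward = None
                node._parents = ()
                if node is not self:
                    node.grad = None

    def _accum(self, grad: np.ndarray):
        # Always copy on first store: the same gradient array may be routed
        # to several parents (e.g. both operands of +), and later in-place
        # accumulation must not alias it.
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype)
        else:
            self.grad += grad

    # ----------------------------------------------------------- arithmetic
    def __add__(self, other):
        return _binop(self, other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binop(self, other, np.subtract, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        return _binop(self, other, np.multiply, lambda g, a, b: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binop(self, other, np.divide,
                      lambda g, a, b: (g / b, -g * a / (b * b)))

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, p: float):
        out = _make(np.power(self.data, p), (self,))
        if out._parents:
            def bwd(g, a=self, p=p):
                a._accum(g * p * np.power(a.data, p - 1.0))
            out._backward = bwd
        return out

    def sqrt(self):
        out = _make(np.sqrt(self.data), (self,))
        if out._parents:
            # capture the array, not the Tensor: avoids a reference cycle
            def bwd(g, a=self, odata=out.data):
                a._accum(g * 0.5 / np.maximum(odata, 1e-12))
            out._backward = bwd
        return out

    def exp(self):
        out = _make(np.exp(self.data), (self,))
        if out._parents:
            def bwd(g, a=self, odata=out.data):
                a._accum(g * odata)
            out._backward = bwd
        return out

    def clip_min(self, lo: float):
        """max(x, lo); subgradient 0 below lo."""
        out = _make(np.maximum(self.data, lo), (self,))
        if out._parents:
            mask = (self.data > lo).astype(self.data.dtype)
            def bwd(g, a=self, m=mask):
                a._accum(g * m)
            out._backward = bwd
        return out

    # ---------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            shape = self.data.shape
            def bwd(g, a=self, axis=axis, keepdims=keepdims, shape=shape):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, shape).astype(a.data.dtype))
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        # keep 1/n in this tensor's dtype; a float32-rounded reciprocal
        # would contaminate float64 reductions
        inv = Tensor(np.asarray(1.0 / float(n)), dtype=self.data.dtype)
        return self.sum(axis=axis, keepdims=keepdims) * inv

    # --------------------------------------------------------------- shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out._parents:
            orig = self.data.shape
            def bwd(g, a=self, orig=orig):
                a._accum(g.reshape(orig))
            out._backward = bwd
        return out

    def transpose(self, *axes):
        out = _make(self.data.transpose(axes), (self,))
        if out._parents:
            inv = tuple(np.argsort(axes))
            def bwd(g, a=self, inv=inv):
                a._accum(np.ascontiguousarray(g.transpose(inv)))
            out._backward = bwd
        return out

    def roll(self, shifts: tuple[int, int], axes: tuple[int, int]):
        out = _make(np.roll(self.data, shifts, axis=axes), (self,))
        if out._parents:
            neg = tuple(-s for s in shifts)
            def bwd(g, a=self, neg=neg, axes=axes):
                a._accum(np.roll(g, neg, axis=axes))
            out._backward = bwd
        return out

    def pad2d(self, pads: tuple[int, int, int, int], mode: str = "constant"):
        """Pad last two axes by (top, bottom, left, right).

        Non-constant modes (reflect/edge/wrap) are realized as an index
        gather so the backward pass scatter-adds gradient from padded
        pixels to their interior sources.
        """
        t, b, l, r = pads
        H, W = self.data.shape[-2:]
        if mode == "constant":
            width = [(0, 0)] * (self.ndim - 2) + [(t, b), (l, r)]
            out = _make(np.pad(self.data, width), (self,))
            if out._parents:
                def bwd(g, a=self, t=t, l=l, H=H, W=W):
                    a._accum(np.ascontiguousarray(g[..., t:t + H, l:l + W]))
                out._backward = bwd
            return out
        idx_h = np.pad(np.arange(H), (t, b), mode=mode)
        idx_w = np.pad(np.arange(W), (l, r), mode=mode)
        out = _make(np.ascontiguousarray(
            self.data[..., idx_h[:, None], idx_w[None, :]]), (self,))
        if out._parents:
            flat_src = (idx_h[:, None] * W + idx_w[None, :]).reshape(-1)
            def bwd(g, a=self, flat_src=flat_src, H=H, W=W):
                lead = g.shape[:-2]
                gx = np.zeros(lead + (H * W,), dtype=g.dtype)
                np.add.at(gx, (..., flat_src), g.reshape(lead + (-1,)))
                a._accum(gx.reshape(lead + (H, W)))
            out._backward = bwd
        return out

    def crop2d(self, H: int, W: int):
        """Take the top-left H x W corner of the last two axes."""
        out = _make(np.ascontiguousarray(self.data[..., :H, :W]), (self,))
        if out._parents:
            shape = self.data.shape
            def bwd(g, a=self, shape=shape, H=H, W=W):
                full = np.zeros(shape, dtype=g.dtype)
                full[..., :H, :W] = g
                a._accum(full)
            out._backward = bwd
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out._parents:
            def bwd(g, a=self, b=other):
                if a.requires_grad or a._parents:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                    a._accum(_unbroadcast(ga, a.data.shape))
                if b.requires_grad or b._parents:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                    b._accum(_unbroadcast(gb, b.data.shape))
            out._backward = bwd
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_graph(*ts: Tensor) -> bool:
    return _GRAD_ENABLED and any(t.requires_grad or t._parents for t in ts)


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data, dtype=data.dtype)
    if _needs_graph(*parents):
        out._parents = tuple(parents)
    return out


def _binop(a: Tensor, b, fwd, grads) -> Tensor:
    b = _as_tensor(b)
    out = _make(fwd(a.data, b.data), (a, b))
    if out._parents:
        def bwd(g, a=a, b=b, grads=grads):
            ga, gb = grads(g, a.data, b.data)
            if a.requires_grad or a._parents:
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad or b._parents:
                gb_arr = np.asarray(gb, dtype=b.data.dtype)
                b._accum(_unbroadcast(gb_arr, b.data.shape))
        out._backward = bwd
    return out


def cast(x: Tensor, dtype) -> Tensor:
    """Change dtype; gradient is cast back to the input dtype."""
    if x.data.dtype == dtype:
        return x
    out = _make(x.data.astype(dtype), (x,))
    if out._parents:
        def bwd(g, x=x):
            x._accum(g.astype(x.data.dtype))
        out._backward = bwd
    return out


def concatenate(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in ts], axis=axis), ts)
    if out._parents:
        sizes = [t.data.shape[axis] for t in ts]
        splits = np.cumsum(sizes)[:-1]
        def bwd(g, ts=ts, splits=splits, axis=axis):
            for t, piece in zip(ts, np.split(g, splits, axis=axis)):
                if t.requires_grad or t._parents:
                    t._accum(np.ascontiguousarray(piece))
        out._backward = bwd
    return out


# ------------------------------------------------------------ fused non-lin
_SQRT2 = np.float32(np.sqrt(2.0))
_INV_SQRT_2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))


def gelu(x: Tensor) -> Tensor:
    """Exact GELU: x * Phi(x) with Phi the standard normal CDF."""
    cdf = 0.5 * (1.0 + erf(x.data / _SQRT2))
    out = _make((x.data * cdf).astype(x.data.dtype), (x,))
    if out._parents:
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x.data * x.data)
        dg = (cdf + x.data * pdf).astype(x.data.dtype)
        def bwd(g, x=x, dg=dg):
            x._accum(g * dg)
        out._backward = bwd
    return out


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    out = _make(np.where(x.data >= 0, x.data, slope * x.data), (x,))
    if out._parents:
        d = np.where(x.data >= 0, 1.0, slope).astype(x.data.dtype)
        def bwd(g, x=x, d=d):
            x._accum(g * d)
        out._backward = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = _make(y.astype(x.data.dtype), (x,))
    if out._parents:
        def bwd(g, x=x, y=out.data, axis=axis):
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accum(y * (g - dot))
        out._backward = bwd
    return out


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift per channel."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = _make((xhat * weight.data + bias.data).astype(x.data.dtype),
                (x, weight, bias))
    if out._parents:
        C = x.data.shape[-1]
        def bwd(g, x=x, w=weight, b=bias, xhat=xhat, inv=inv, C=C):
            if b.requires_grad or b._parents:
                b._accum(_unbroadcast(g, b.data.shape))
            if w.requires_grad or w._parents:
                w._accum(_unbroadcast(g * xhat, w.data.shape))
            if x.requires_grad or x._parents:
                gh = g * w.data
                m1 = gh.mean(axis=-1, keepdims=True)
                m2 = (gh * xhat).mean(axis=-1, keepdims=True)
                x._accum(inv * (gh - m1 - xhat * m2))
        out._backward = bwd
    return out


def gather_rows(table: Tensor, index: np.ndarray) -> Tensor:
    """table[index] for an integer index array; scatter-add on backward."""
    out = _make(table.data[index], (table,))
    if out._parents:
        def bwd(g, t=table, index=index):
            acc = np.zeros_like(t.data)
            np.add.at(acc, index.reshape(-1),
                      g.reshape(-1, *t.data.shape[1:]))
            t._accum(acc)
        out._backward = bwd
    return out


# ------------------------------------------------------------- convolutions
def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> contiguous (N*Ho*Wo, C*kh*kw) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # N,C,Ho,Wo,kh,kw
    N, C, Ho, Wo = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(N * Ho * Wo, C * kh * kw), (N, C, Ho, Wo)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """NCHW convolution via im2col + GEMM; w is (Cout, Cin, kh, kw)."""
    N, Cin, H, W = x.data.shape
    Cout, _, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2)) \
        if padding else x.data
    cols, (_, _, Ho, Wo) = _im2col(xp, kh, kw, stride)
    wm = w.data.reshape(Cout, -1)
    y = (cols @ wm.T).reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2)
    y = np.ascontiguousarray(y)
    if b is not None:
        y += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _make(y, parents)
    if out._parents:
        def bwd(g, x=x, w=w, b=b, cols=cols, xp_shape=xp.shape,
                stride=stride, padding=padding, kh=kh, kw=kw,
                H=H, W=W, Ho=Ho, Wo=Wo, N=N, Cout=Cout):
            gm = np.ascontiguousarray(
                g.transpose(0, 2, 3, 1)).reshape(-1, Cout)
            if b is not None and (b.requires_grad or b._parents):
                b._accum(gm.sum(axis=0))
            if w.requires_grad or w._parents:
                w._accum((gm.T @ cols).reshape(w.data.shape))
            if x.requires_grad or x._parents:
                gcols = (gm @ w.data.reshape(Cout, -1)).reshape(
                    N, Ho, Wo, -1, kh, kw).transpose(0, 3, 1, 2, 4, 5)
                gxp = np.zeros(xp_shape, dtype=g.dtype)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + stride * Ho:stride,
                            j:j + stride * Wo:stride] += gcols[..., i, j]
                if padding:
                    gxp = gxp[:, :, padding:padding + H, padding:padding + W]
                x._accum(np.ascontiguousarray(gxp))
        out._backward = bwd
    return out


def depthwise_conv3x3(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Per-channel 3x3 convolution, same padding; w is (C, 3, 3).

    Realized as nine shifted multiply-adds, which beats patch extraction
    for this kernel size.
    """
    N, C, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    y = np.zeros_like(x.data)
    for i in range(3):
        for j in range(3):
            y += w.data[None, :, i, j, None, None] * \
                xp[:, :, i:i + H, j:j + W]
    if b is not None:
        y += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _make(y, parents)
    if out._parents:
        def bwd(g, x=x, w=w, b=b, xp=xp, H=H, W=W):
            if b is not None and (b.requires_grad or b._parents):
                b._accum(g.sum(axis=(0, 2, 3)))
            if w.requires_grad or w._parents:
                gw = np.empty_like(w.data)
                for i in range(3):
                    for j in range(3):
                        gw[:, i, j] = np.einsum(
                            "nchw,nchw->c", g, xp[:, :, i:i + H, j:j + W])
                w._accum(gw)
            if x.requires_grad or x._parents:
                gxp = np.zeros(xp.shape, dtype=g.dtype)
                for i in range(3):
                    for j in range(3):
                        gxp[:, :, i:i + H, j:j + W] += \
                            g * w.data[None, :, i, j, None, None]
                x._accum(np.ascontiguousarray(gxp[:, :, 1:1 + H, 1:1 + W]))
        out._backward = bwd
    return out


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x2 stride-2 transposed convolution (exact 2x upsampling).

    Kernel and stride coincide, so output pixels partition into disjoint
    2x2 blocks and the operation is a channel mix followed by a reshape.
    w is (Cin, Cout, 2, 2).
    """
    N, Cin, H, W = x.data.shape
    Cout = w.data.shape[1]
    xm = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1)).reshape(-1, Cin)
    wm = w.data.reshape(Cin, -1)                   # Cin, Cout*4
    t = (xm @ wm).reshape(N, H, W, Cout, 2, 2)
    y = np.ascontiguousarray(
        t.transpose(0, 3, 1, 4, 2, 5)).reshape(N, Cout, 2 * H, 2 * W)
    if b is not None:
        y += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _make(y, parents)
    if out._parents:
        def bwd(g, x=x, w=w, b=b, xm=xm, N=N, Cin=Cin, Cout=Cout, H=H, W=W):
            gr = np.ascontiguousarray(
                g.reshape(N, Cout, H, 2, W, 2).transpose(0, 2, 4, 1, 3, 5)
            ).reshape(-1, Cout * 4)                # (N*H*W, Cout*4)
            if b is not None and (b.requires_grad or b._parents):
                b._accum(g.sum(axis=(0, 2, 3)))
            if w.requires_grad or w._parents:
                w._accum((xm.T @ gr).reshape(w.data.shape))
            if x.requires_grad or x._parents:
                gx = (gr @ w.data.reshape(Cin, -1).T).reshape(N, H, W, Cin)
                x._accum(np.ascontiguousarray(gx.transpose(0, 3, 1, 2)))
        out._backward = bwd
    return out


def avg_pool2x2(x: Tensor) -> Tensor:
    """2x2 mean pooling with stride 2 (even spatial dims required)."""
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"avg_pool2x2 needs even dims, got {H}x{W}")
    y = x.data.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
    out = _make(y.astype(x.data.dtype), (x,))
    if out._parents:
        def bwd(g, x=x, H=H, W=W):
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            x._accum(gx.astype(x.data.dtype))
        out._backward = bwd
    return out
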