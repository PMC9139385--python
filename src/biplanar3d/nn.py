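"""Compact CPU tensor stack: reverse-mode autodiff plus the handful of
layers the reconstruction network needs (2D/3D convolution, batch norm,
max pooling, nearest-neighbour upsampling, Adam).

Everything is plain numpy.  Convolutions are evaluated as
``sliding_window_view`` + ``tensordot`` (an im2col matmul in disguise);
the input gradient is computed as a stride-dilated transposed
convolution, so no scatter-add appears anywhere and the whole stack is
deterministic.  Layers default to float32; the autodiff ops preserve
whatever dtype flows in, which lets the tests gradient-check in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "Parameter", "add", "mul", "scale", "concat", "relu",
    "leaky_relu", "sigmoid", "mean_sq", "mean_sq_diff", "tile_along",
    "permute", "reshape", "Conv", "BatchNorm", "MaxPool2x", "UpsampleNearest",
    "Adam",
]


# ---------------------------------------------------------------------------
# autodiff core

class Tensor:
    """A node in the computation tape."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self, seed=None):
        """Reverse sweep from this node; accumulates ``.grad`` on the tape."""
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
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
        if seed is None:
            seed = np.ones_like(self.data)
        self.grad = np.asarray(seed, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _unary(x, out, dfun):
    def bw(g):
        x.accumulate(dfun(g))
    return Tensor(out, (x,), bw)


# ---------------------------------------------------------------------------
# elementwise / structural ops

def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data
    def bw(g):
        a.accumulate(g)
        b.accumulate(g)
    return Tensor(out, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data
    def bw(g):
        a.accumulate(g * b.data)
        b.accumulate(g * a.data)
    return Tensor(out, (a, b), bw)


def scale(x: Tensor, c: float) -> Tensor:
    return _unary(x, x.data * c, lambda g: g * c)


def relu(x: Tensor) -> Tensor:
    m = x.data > 0
    return _unary(x, x.data * m, lambda g: g * m)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    f = np.where(x.data > 0, 1.0, slope).astype(x.data.dtype)
    return _unary(x, x.data * f, lambda g: g * f)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return _unary(x, s, lambda g: g * s * (1.0 - s))


def concat(xs, axis: int = 1) -> Tensor:
    out = np.concatenate([x.data for x in xs], axis=axis)
    sizes = [x.data.shape[axis] for x in xs]
    splits = np.cumsum(sizes)[:-1]
    def bw(g):
        for x, piece in zip(xs, np.split(g, splits, axis=axis)):
            x.accumulate(piece)
    return Tensor(out, tuple(xs), bw)


def mean_sq(x: Tensor, shift: float = 0.0) -> Tensor:
    """mean((x - shift)^2) as a scalar tensor."""
    d = x.data - shift
    out = np.mean(d * d)
    n = d.size
    def bw(g):
        x.accumulate((2.0 / n) * d * g)
    return Tensor(out, (x,), bw)


def mean_sq_diff(x: Tensor, target: np.ndarray) -> Tensor:
    """mean((x - target)^2) against a constant target."""
    d = x.data - target
    out = np.mean(d * d)
    n = d.size
    def bw(g):
        x.accumulate((2.0 / n) * d * g)
    return Tensor(out, (x,), bw)


def tile_along(x: Tensor, axis: int, reps: int) -> Tensor:
    """Insert a new axis of size ``reps`` at ``axis`` by broadcasting."""
    out = np.repeat(np.expand_dims(x.data, axis), reps, axis=axis)
    def bw(g):
        x.accumulate(g.sum(axis=axis))
    return Tensor(out, (x,), bw)


def permute(x: Tensor, order) -> Tensor:
    order = tuple(order)
    inv = tuple(np.argsort(order))
    return _unary(x, np.transpose(x.data, order),
                  lambda g: np.transpose(g, inv))


def reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape
    return _unary(x, x.data.reshape(shape), lambda g: g.reshape(old))


def average(xs) -> Tensor:
    out = sum(x.data for x in xs) / len(xs)
    inv = 1.0 / len(xs)
    def bw(g):
        for x in xs:
            x.accumulate(g * inv)
    return Tensor(out, tuple(xs), bw)


# ---------------------------------------------------------------------------
# convolution
#
# The hot path is im2col in channels-last layout: each kernel offset is one
# strided slice-copy with long contiguous runs, followed by a single GEMM.

from itertools import product as _product

#: keep the im2col buffer for the backward pass when it is smaller than this
_COL_CACHE_BYTES = 96 * 2 ** 20


def _offsets(kernel):
    return list(_product(*[range(k) for k in kernel]))


def _offset_slice(offs, stride, out_spatial):
    return tuple(slice(offs[i], offs[i] + (out_spatial[i] - 1) * stride[i]
                       + 1, stride[i]) for i in range(len(offs)))


def _im2col(xt, kernel, stride, out_spatial):
    """Channels-last padded input (N, *Sp, C) -> (K, N, *S_out, C).

    Offset-major layout: each kernel offset is one contiguous block, so
    both the gather here and the per-offset GEMMs run at memcpy/BLAS
    speed.
    """
    n, c = xt.shape[0], xt.shape[-1]
    kprod = int(np.prod(kernel))
    col = np.empty((kprod, n) + tuple(out_spatial) + (c,), dtype=xt.dtype)
    for j, offs in enumerate(_offsets(kernel)):
        sl = _offset_slice(offs, stride, out_spatial)
        col[j] = xt[(slice(None),) + sl + (slice(None),)]
    return col


def _conv_nd(x, w, stride, pad, want_cache=False):
    """Correlate x:(N,C,*S) with w:(O,C,*K); pad is ((lo,hi),...) per axis.

    Returns (y, cache) with y:(N,O,*S_out); cache feeds the weight
    gradient and is either the col buffer or the transposed input.
    """
    nd = x.ndim - 2
    kernel = w.shape[2:]
    n, o = x.shape[0], w.shape[0]
    c = w.shape[1]
    xp = np.pad(x, [(0, 0), (0, 0)] + list(pad)) if any(
        p != (0, 0) for p in pad) else x
    xt = np.ascontiguousarray(np.moveaxis(xp, 1, -1))
    out_spatial = tuple(
        (xp.shape[2 + i] - kernel[i]) // stride[i] + 1 for i in range(nd))
    col = _im2col(xt, kernel, stride, out_spatial)
    kprod = col.shape[0]
    y = np.zeros((col[0].size // c, o), dtype=x.dtype)
    wk = w.reshape(o, c, kprod)
    for j in range(kprod):
        y += col[j].reshape(-1, c) @ wk[:, :, j].T
    y = y.reshape((n,) + out_spatial + (o,))
    y = np.ascontiguousarray(np.moveaxis(y, -1, 1))
    cache = None
    if want_cache:
        cache = (("col", col) if col.nbytes <= _COL_CACHE_BYTES
                 else ("xt", xt))
    return y, cache


def _conv_grad_w(cache, gy, w_shape, stride):
    """dW[o,c,*k] from the forward cache and the output gradient."""
    nd = len(w_shape) - 2
    kernel = w_shape[2:]
    kind, data = cache
    if kind == "col":
        col = data
    else:
        col = _im2col(data, kernel, stride, gy.shape[2:])
    o, c = w_shape[0], w_shape[1]
    kprod = col.shape[0]
    gyt = np.ascontiguousarray(np.moveaxis(gy, 1, -1)).reshape(-1, o)
    dw = np.empty((o, c, kprod), dtype=gy.dtype)
    for j in range(kprod):
        dw[:, :, j] = gyt.T @ col[j].reshape(-1, c)
    return dw.reshape(w_shape)


def _conv_grad_x(gy, w, stride, pad, in_spatial):
    """Input gradient by direct scatter: a GEMM per kernel offset, then a
    strided accumulation (the exact adjoint of _im2col)."""
    nd = gy.ndim - 2
    kernel = w.shape[2:]
    n, o = gy.shape[0], gy.shape[1]
    c = w.shape[1]
    out_spatial = gy.shape[2:]
    padded = tuple(in_spatial[i] + pad[i][0] + pad[i][1] for i in range(nd))
    gyt = np.ascontiguousarray(np.moveaxis(gy, 1, -1)).reshape(-1, o)
    kprod = int(np.prod(kernel))
    wk = w.reshape(o, c, kprod)
    dxt = np.zeros((n,) + padded + (c,), dtype=gy.dtype)
    block_shape = (n,) + tuple(out_spatial) + (c,)
    for j, offs in enumerate(_offsets(kernel)):
        sl = _offset_slice(offs, stride, out_spatial)
        contrib = (gyt @ wk[:, :, j]).reshape(block_shape)
        dxt[(slice(None),) + sl + (slice(None),)] += contrib
    dx = np.moveaxis(dxt, -1, 1)
    crop = tuple(slice(pad[i][0], pad[i][0] + in_spatial[i])
                 for i in range(nd))
    return np.ascontiguousarray(dx[(slice(None), slice(None)) + crop])


# -- space-to-depth fast path for stride-2 even-kernel convolutions -------
#
# A stride-2 convolution with an even kernel equals a stride-1 convolution
# with half the kernel on the phase-split input (each spatial axis split
# into even/odd phases stacked as channels).  This replaces K scattered
# offset-copies with K/2^nd long-run copies and gives GEMMs a fat inner
# dimension, which matters on memory-bandwidth-bound hosts.

def _s2d(xp):
    """(N, C, *L) with even spatial sizes -> (N, 2^nd * C, *L/2);
    channel order (phase_0, ..., phase_{nd-1}, c)."""
    nd = xp.ndim - 2
    n, c = xp.shape[:2]
    shape = [n, c]
    for L in xp.shape[2:]:
        shape += [L // 2, 2]
    xr = xp.reshape(shape)
    phase_axes = tuple(3 + 2 * i for i in range(nd))
    half_axes = tuple(2 + 2 * i for i in range(nd))
    xr = np.transpose(xr, (0,) + phase_axes + (1,) + half_axes)
    return np.ascontiguousarray(xr).reshape(
        (n, (2 ** nd) * c) + tuple(L // 2 for L in xp.shape[2:]))


def _s2d_inv(xs, orig_shape):
    """Adjoint of _s2d (exact inverse for the same shapes)."""
    nd = len(orig_shape) - 2
    n, c = orig_shape[:2]
    halves = [L // 2 for L in orig_shape[2:]]
    xr = xs.reshape([n] + [2] * nd + [c] + halves)
    # back to (N, C, h0, 2, h1, 2, ...)
    order = [0, nd + 1]
    for i in range(nd):
        order += [nd + 2 + i, 1 + i]
    xr = np.transpose(xr, order)
    return np.ascontiguousarray(xr).reshape(orig_shape)


def _w_s2d(w):
    """(O, C, *K) with even K -> (O, 2^nd * C, *K/2) in _s2d channel order."""
    nd = w.ndim - 2
    o, c = w.shape[:2]
    shape = [o, c]
    for k in w.shape[2:]:
        shape += [k // 2, 2]          # (j, phase): k = phase + 2j
    wr = w.reshape(shape)
    phase_axes = tuple(3 + 2 * i for i in range(nd))
    j_axes = tuple(2 + 2 * i for i in range(nd))
    wr = np.transpose(wr, (0,) + phase_axes + (1,) + j_axes)
    return np.ascontiguousarray(wr).reshape(
        (o, (2 ** nd) * c) + tuple(k // 2 for k in w.shape[2:]))


def _w_s2d_inv(ws, orig_shape):
    nd = len(orig_shape) - 2
    o, c = orig_shape[:2]
    wr = ws.reshape([o] + [2] * nd + [c] + [k // 2 for k in orig_shape[2:]])
    order = [0, nd + 1]
    for i in range(nd):
        order += [nd + 2 + i, 1 + i]
    wr = np.transpose(wr, order)
    return np.ascontiguousarray(wr).reshape(orig_shape)


def _s2d_applicable(x, w, stride, pad):
    nd = x.ndim - 2
    return (all(s == 2 for s in stride)
            and all(k % 2 == 0 for k in w.shape[2:])
            and all((x.shape[2 + i] + pad[i][0] + pad[i][1]) % 2 == 0
                    for i in range(nd)))


def conv(x: Tensor, w: Parameter, b: Parameter, stride, pad) -> Tensor:
    """N-dimensional strided correlation with bias.

    ``pad`` is a per-spatial-axis (lo, hi) tuple; (S + lo + hi - K) must be
    divisible by the stride so the transposed-convolution gradient tiles
    the input exactly.
    """
    nd = x.data.ndim - 2
    stride = tuple(stride)
    pad = tuple(tuple(p) for p in pad)
    for i in range(nd):
        if (x.data.shape[2 + i] + pad[i][0] + pad[i][1]
                - w.data.shape[2 + i]) % stride[i]:
            raise ValueError("conv geometry not stride-aligned")
    in_spatial = x.data.shape[2:]
    w_shape = w.data.shape
    s2d = _s2d_applicable(x.data, w.data, stride, pad)
    if s2d:
        xp = np.pad(x.data, [(0, 0), (0, 0)] + list(pad)) if any(
            p != (0, 0) for p in pad) else x.data
        xs = _s2d(xp)
        ws = _w_s2d(w.data)
        zero_pad = ((0, 0),) * nd
        ones = (1,) * nd
        y, cache = _conv_nd(xs, ws, ones, zero_pad,
                            want_cache=w.requires_grad)
        xp_shape, xs_spatial, ws_shape = xp.shape, xs.shape[2:], ws.shape
    else:
        y, cache = _conv_nd(x.data, w.data, stride, pad,
                            want_cache=w.requires_grad)
    y += b.data.reshape((1, -1) + (1,) * nd)

    def bw(g):
        g = np.ascontiguousarray(g)
        need_dx = x.requires_grad or x._parents
        if s2d:
            if w.requires_grad:
                dws = _conv_grad_w(cache, g, ws_shape, (1,) * nd)
                w.accumulate(_w_s2d_inv(dws, w_shape))
                b.accumulate(g.sum(axis=(0,) + tuple(range(2, 2 + nd))))
            if need_dx:
                dxs = _conv_grad_x(g, ws, (1,) * nd, ((0, 0),) * nd,
                                   xs_spatial)
                dxp = _s2d_inv(dxs, xp_shape)
                crop = tuple(slice(pad[i][0], pad[i][0] + in_spatial[i])
                             for i in range(nd))
                x.accumulate(np.ascontiguousarray(
                    dxp[(slice(None), slice(None)) + crop]))
        else:
            if w.requires_grad:
                w.accumulate(_conv_grad_w(cache, g, w_shape, stride))
                b.accumulate(g.sum(axis=(0,) + tuple(range(2, 2 + nd))))
            if need_dx:
                x.accumulate(_conv_grad_x(g, w.data, stride, pad,
                                          in_spatial))
    return Tensor(y, (x, w, b), bw)


class Conv:
    """Convolution layer (2D or 3D by kernel rank) with He-style init."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, rng=None,
                 dtype=np.float32, bias_init=0.0):
        if np.isscalar(kernel):
            raise ValueError("kernel must be a tuple (one entry per axis)")
        kernel = tuple(kernel)
        nd = len(kernel)
        stride = (stride,) * nd if np.isscalar(stride) else tuple(stride)
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * int(np.prod(kernel))
        wdata = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(out_ch, in_ch) + kernel).astype(dtype)
        self.w = Parameter(wdata)
        self.b = Parameter(np.full(out_ch, bias_init, dtype=dtype))
        self.stride = stride
        # Padding keeps S_out = S/stride for stride-divisible S: odd kernels
        # get symmetric k//2; even kernels get (k//2-1, k//2) at stride 1
        # and (k//2-1, k//2-1) at stride 2.
        pads = []
        for k, s in zip(kernel, stride):
            if k % 2:
                pads.append((k // 2, k // 2))
            elif s == 1:
                pads.append((k // 2 - 1, k // 2))
            else:
                pads.append((k // 2 - 1, k // 2 - 1))
        self.pad = tuple(pads)

    def __call__(self, x: Tensor) -> Tensor:
        return conv(x, self.w, self.b, self.stride, self.pad)

    def params(self):
        return [self.w, self.b]


class BatchNorm:
    """Per-channel batch normalization over (N, *spatial)."""

    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float32):
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train: bool = True) -> Tensor:
        nd = x.data.ndim - 2
        shape = (1, -1) + (1,) * nd
        axes = (0,) + tuple(range(2, 2 + nd))
        if train:
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean = self.running_mean.astype(x.data.dtype)
            var = self.running_var.astype(x.data.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean.reshape(shape)) * inv.reshape(shape)
        out = self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)
        gamma, beta = self.gamma, self.beta
        n = x.data.size // x.data.shape[1]

        def bw(g):
            gamma.accumulate((g * xhat).sum(axis=axes))
            beta.accumulate(g.sum(axis=axes))
            if train:
                gi = inv.reshape(shape) * gamma.data.reshape(shape) * (
                    g - g.mean(axis=axes).reshape(shape)
                    - xhat * (g * xhat).mean(axis=axes).reshape(shape))
            else:
                gi = inv.reshape(shape) * gamma.data.reshape(shape) * g
            x.accumulate(gi.astype(x.data.dtype))
        _ = n
        return Tensor(out.astype(x.data.dtype), (x, gamma, beta), bw)

    def params(self):
        return [self.gamma, self.beta]


class MaxPool2x:
    """Non-overlapping max pooling with window 2 along every spatial axis."""

    def __call__(self, x: Tensor) -> Tensor:
        nd = x.data.ndim - 2
        spatial = x.data.shape[2:]
        if any(s % 2 for s in spatial):
            raise ValueError("MaxPool2x needs even spatial sizes")
        newshape = x.data.shape[:2]
        for s in spatial:
            newshape += (s // 2, 2)
        xr = x.data.reshape(newshape)
        # bring the window axes last and flatten them
        win_axes = tuple(3 + 2 * i for i in range(nd))
        keep_axes = (0, 1) + tuple(2 + 2 * i for i in range(nd))
        xr = np.transpose(xr, keep_axes + win_axes)
        flat = xr.reshape(xr.shape[:2 + nd] + (2 ** nd,))
        idx = np.argmax(flat, axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

        def bw(g):
            gf = np.zeros_like(flat)
            np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
            gr = gf.reshape(xr.shape)
            inv = np.argsort(keep_axes + win_axes)
            gx = np.transpose(gr, inv).reshape(x.data.shape)
            x.accumulate(gx)
        return Tensor(out, (x,), bw)


class UpsampleNearest:
    """Nearest-neighbour upsampling by 2 along every spatial axis."""

    def __call__(self, x: Tensor) -> Tensor:
        nd = x.data.ndim - 2
        out = x.data
        for ax in range(2, 2 + nd):
            out = np.repeat(out, 2, axis=ax)

        def bw(g):
            for ax in range(2, 2 + nd):
                sh = g.shape[:ax] + (g.shape[ax] // 2, 2) + g.shape[ax + 1:]
                g = g.reshape(sh).sum(axis=ax + 1)
            x.accumulate(g)
        return Tensor(out, (x,), bw)


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Adaptive-moment optimizer (decoupled per-parameter state)."""

    def __init__(self, params, lr=2e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            mh = m / (1.0 - self.b1 ** self.t)
            vh = v / (1.0 - self.b2 ** self.t)
            p.data = (p.data - self.lr * mh / (np.sqrt(vh) + self.eps)
                      ).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
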