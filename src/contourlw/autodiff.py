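"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks in this package (contour refinement and weight regression) are
small enough that a compact tape-based engine is sufficient: dense matrix
products, 2-D convolutions via im2col, bilinear feature sampling, and the
usual pointwise nonlinearities.  Gradients flow through a dynamically built
graph; ``Tensor.backward`` accepts an arbitrary seed gradient so externally
computed gradients (e.g. the analytic optimal-transport gradients) can be
injected at any node.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "conv2d", "grid_sample", "upsample_nearest"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._prev for p in prev):
            out.requires_grad = True
            out._prev = tuple(prev)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=np.float64)
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(grad)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        return self._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bwd)

    def __matmul__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            self._accum(_unbroadcast(ga, self.data.shape))
            other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(np.matmul(self.data, other.data), (self, other), bwd)

    # ------------------------------------------------------------- pointwise
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accum(g * 0.5 / np.maximum(out_data, 1e-300))

        return self._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bwd)

    def leaky_relu(self, slope: float = 0.01):
        factor = np.where(self.data > 0, 1.0, slope)

        def bwd(g):
            self._accum(g * factor)

        return self._make(self.data * factor, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bwd)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis=-1):
        # fused forward/backward keeps the big attention temporaries down
        z = self.data - self.data.max(axis=axis, keepdims=True)
        np.exp(z, out=z)
        z /= z.sum(axis=axis, keepdims=True)
        out_data = z

        def bwd(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum((g - dot) * out_data)

        return self._make(out_data, (self,), bwd)

    # ---------------------------------------------------------- shape juggle
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bwd)

    def swapaxes(self, a: int, b: int):
        def bwd(g):
            self._accum(np.swapaxes(g, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(self.data[idx], (self,), bwd)


# -------------------------------------------------------------------- helpers
def concat(tensors, axis=0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad or t._prev for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = bwd
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - kh) // stride + 1
    wo = (x.shape[3] - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    win = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, c, ho, wo, kh, kw),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        writeable=False,
    )
    # (b, ho, wo, c*kh*kw)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho, wo, c * kh * kw), ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, via im2col."""
    bs, cin, h, ww = x.data.shape
    cout, cin2, kh, kw = w.data.shape
    assert cin == cin2, "channel mismatch"
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(cout, -1)
    out_data = cols @ wmat.T  # (b, ho, wo, cout)
    if b is not None:
        out_data = out_data + b.data
    out_data = out_data.transpose(0, 3, 1, 2)

    def bwd(g):
        gout = g.transpose(0, 2, 3, 1)  # (b,ho,wo,cout)
        gw = np.tensordot(gout, cols, axes=([0, 1, 2], [0, 1, 2]))  # (cout, c*kh*kw)
        w._accum(gw.reshape(w.data.shape))
        if b is not None:
            b._accum(gout.sum(axis=(0, 1, 2)))
        gcols = gout @ wmat  # (b,ho,wo,c*kh*kw)
        gx = np.zeros((bs, cin, h + 2 * pad, ww + 2 * pad))
        gcols = gcols.reshape(bs, ho, wo, cin, kh, kw)
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                    gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        if pad:
            gx = gx[:, :, pad:-pad, pad:-pad]
        x._accum(gx)

    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data)
    if any(p.requires_grad or p._prev for p in prev):
        out.requires_grad = True
        out._prev = prev
        out._backward = bwd
    return out


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour upsampling of an NCHW tensor by an integer factor."""
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)

    def bwd(g):
        b, c, h, w = x.data.shape
        gx = g.reshape(b, c, h, factor, w, factor).sum(axis=(3, 5))
        x._accum(gx)

    return x._make(out_data, (x,), bwd)


def grid_sample(feat: Tensor, coords: Tensor) -> Tensor:
    """Bilinear sampling of a (C, H, W) feature map at K (x, y) locations.

    Coordinates are in pixel units of the feature map, border-clamped.
    Differentiable w.r.t. both the features and the sampling coordinates.
    Returns a (K, C) tensor.
    """
    c, h, w = feat.data.shape
    xy = coords.data
    x = np.clip(xy[:, 0], 0.0, w - 1.0)
    y = np.clip(xy[:, 1], 0.0, h - 1.0)
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    x0 = np.minimum(x0, w - 2) if w > 1 else x0 * 0
    y0 = np.minimum(y0, h - 2) if h > 1 else y0 * 0
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = x - x0
    fy = y - y0
    f00 = feat.data[:, y0, x0]  # (C, K)
    f01 = feat.data[:, y0, x1]
    f10 = feat.data[:, y1, x0]
    f11 = feat.data[:, y1, x1]
    out_data = (
        f00 * (1 - fx) * (1 - fy)
        + f01 * fx * (1 - fy)
        + f10 * (1 - fx) * fy
        + f11 * fx * fy
    ).T  # (K, C)

    # clamp kills the coordinate gradient outside the map
    inx = (xy[:, 0] > 0.0) & (xy[:, 0] < w - 1.0)
    iny = (xy[:, 1] > 0.0) & (xy[:, 1] < h - 1.0)

    def bwd(g):
        gt = g.T  # (C, K)
        gf = np.zeros_like(feat.data)
        np.add.at(gf, (slice(None), y0, x0), gt * (1 - fx) * (1 - fy))
        np.add.at(gf, (slice(None), y0, x1), gt * fx * (1 - fy))
        np.add.at(gf, (slice(None), y1, x0), gt * (1 - fx) * fy)
        np.add.at(gf, (slice(None), y1, x1), gt * fx * fy)
        feat._accum(gf)
        dfdx = (f01 - f00) * (1 - fy) + (f11 - f10) * fy  # (C, K)
        dfdy = (f10 - f00) * (1 - fx) + (f11 - f01) * fx
        gx = (gt * dfdx).sum(axis=0) * inx
        gy = (gt * dfdy).sum(axis=0) * iny
        coords._accum(np.stack([gx, gy], axis=1))

    out = Tensor(out_data)
    if feat.requires_grad or feat._prev or coords.requires_grad or coords._prev:
        out.requires_grad = True
        out._prev = (feat, coords)
        out._backward = bwd
    return out


class Adam:
    """Adam optimizer over a list of Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
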