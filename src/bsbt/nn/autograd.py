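"""A small reverse-mode automatic-differentiation engine on numpy.

Covers exactly the operations the volumetric U-Net needs: elementwise
arithmetic with broadcasting, reductions, the usual activations, 3D
convolution (im2col, chunked along depth to bound memory), 2x max
pooling, and separable linear-interpolation resampling expressed as
per-axis matrix products (so its adjoint is the transposed matrix).

Arrays are channels-first ``(C, D, H, W)`` float32; batching is handled
by looping over samples (volumes are large, batch sizes are 1-2).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _wrap(-1.0)))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, _wrap(-1.0)))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __neg__(self):
        return mul(self, _wrap(-1.0))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- arithmetic ---------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(g, b.data.shape))

    return _node(a.data + b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        a._accum(_unbroadcast(g * b.data, a.data.shape))
        b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _node(a.data * b.data, (a, b), bw)


def div(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        a._accum(_unbroadcast(g / b.data, a.data.shape))
        b._accum(_unbroadcast(-g * a.data / (b.data**2), b.data.shape))

    return _node(a.data / b.data, (a, b), bw)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def bw(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).astype(DTYPE))
            return
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(gg, a.data.shape).astype(DTYPE))

    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)


def tmean(a: Tensor) -> Tensor:
    n = a.data.size
    return mul(tsum(a), _wrap(1.0 / n))


def tabs(a: Tensor) -> Tensor:
    sign = np.sign(a.data)

    def bw(g):
        a._accum(g * sign)

    return _node(np.abs(a.data), (a,), bw)


def texp(a: Tensor) -> Tensor:
    y = np.exp(a.data)

    def bw(g):
        a._accum(g * y)

    return _node(y, (a,), bw)


def tlog(a: Tensor) -> Tensor:
    def bw(g):
        a._accum(g / a.data)

    return _node(np.log(a.data), (a,), bw)


# -- activations --------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bw(g):
        a._accum(g * mask)

    return _node(a.data * mask, (a,), bw)


def elu(a: Tensor, alpha: float = 1.0) -> Tensor:
    pos = a.data > 0
    y = np.where(pos, a.data, alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0))

    def bw(g):
        a._accum(g * np.where(pos, 1.0, y + alpha).astype(DTYPE))

    return _node(y, (a,), bw)


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)

    def bw(g):
        a._accum(g * (1.0 - y**2))

    return _node(y, (a,), bw)


def sigmoid(a: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        a._accum(g * y * (1.0 - y))

    return _node(y, (a,), bw)


def softmax_channels(a: Tensor) -> Tensor:
    """Softmax over axis 0 (the label/channel axis)."""
    z = a.data - a.data.max(axis=0, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=0, keepdims=True)

    def bw(g):
        dot = (g * y).sum(axis=0, keepdims=True)
        a._accum(y * (g - dot))

    return _node(y, (a,), bw)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[0]

    def bw(g):
        a._accum(g[:ca])
        b._accum(g[ca:])

    return _node(np.concatenate([a.data, b.data], axis=0), (a, b), bw)


# -- convolution --------------------------------------------------------

def _conv3d_raw(x: np.ndarray, wmat: np.ndarray, k: int, chunk: int = 8) -> np.ndarray:
    """Same-padded valid correlation: x (Cin,D,H,W) with wmat (Cout, Cin*k^3)."""
    cin, D, H, W = x.shape
    cout = wmat.shape[0]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    out = np.empty((cout, D, H, W), dtype=DTYPE)
    wT = wmat.T  # (Cin*k^3, Cout)
    from numpy.lib.stride_tricks import sliding_window_view

    view = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))  # (Cin,D,H,W,k,k,k)
    for d0 in range(0, D, chunk):
        d1 = min(d0 + chunk, D)
        patch = view[:, d0:d1]                       # (Cin, cd, H, W, k,k,k)
        patch = patch.transpose(1, 2, 3, 0, 4, 5, 6).reshape(
            (d1 - d0) * H * W, cin * k**3
        )
        out[:, d0:d1] = (
            (patch @ wT).reshape(d1 - d0, H, W, cout).transpose(3, 0, 1, 2)
        )
    return out


def _conv3d_grad_w(x: np.ndarray, gy: np.ndarray, k: int, chunk: int = 8) -> np.ndarray:
    """d(loss)/d(wmat): (Cout, Cin*k^3)."""
    cin, D, H, W = x.shape
    cout = gy.shape[0]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    from numpy.lib.stride_tricks import sliding_window_view

    view = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    gw = np.zeros((cout, cin * k**3), dtype=DTYPE)
    for d0 in range(0, D, chunk):
        d1 = min(d0 + chunk, D)
        patch = view[:, d0:d1].transpose(1, 2, 3, 0, 4, 5, 6).reshape(
            (d1 - d0) * H * W, cin * k**3
        )
        gchunk = gy[:, d0:d1].reshape(cout, -1)      # (Cout, cd*H*W)
        gw += gchunk @ patch
    return gw


def conv3d(x: Tensor, w: Tensor, b: Tensor, k: int) -> Tensor:
    """3D convolution, stride 1, same (zero) padding, odd kernel ``k``.

    ``w`` has shape (Cout, Cin, k, k, k); ``b`` shape (Cout,).
    """
    cout, cin = w.data.shape[:2]
    wmat = w.data.reshape(cout, cin * k**3)
    y = _conv3d_raw(x.data, wmat, k) + b.data[:, None, None, None]

    def bw(g):
        g = g.astype(DTYPE)
        if b.requires_grad:
            b._accum(g.sum(axis=(1, 2, 3)))
        if w.requires_grad:
            w._accum(_conv3d_grad_w(x.data, g, k).reshape(w.data.shape))
        if x.requires_grad or x._parents:
            # input gradient = correlation of g with the spatially flipped,
            # in/out-transposed kernel
            wrot = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            wrot_mat = np.ascontiguousarray(wrot).reshape(cin, cout * k**3)
            x._accum(_conv3d_raw(g, wrot_mat, k))

    return _node(y, (x, w, b), bw)


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling, stride 2; spatial dims must be even."""
    C, D, H, W = x.data.shape
    xr = (
        x.data.reshape(C, D // 2, 2, H // 2, 2, W // 2, 2)
        .transpose(0, 1, 3, 5, 2, 4, 6)
        .reshape(C, D // 2, H // 2, W // 2, 8)
    )
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gx = np.zeros((C, D // 2, H // 2, W // 2, 8), dtype=DTYPE)
        np.put_along_axis(gx, idx[..., None], g[..., None], axis=-1)
        gx = (
            gx.reshape(C, D // 2, H // 2, W // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(C, D, H, W)
        )
        x._accum(gx)

    return _node(y, (x,), bw)


_INTERP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Linear-interpolation matrix (n_out, n_in), cell-centered, edge-clamped."""
    key = (n_in, n_out)
    if key in _INTERP_CACHE:
        return _INTERP_CACHE[key]
    M = np.zeros((n_out, n_in), dtype=DTYPE)
    coords = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    i0 = np.clip(np.floor(coords).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    frac = np.clip(coords - np.floor(coords), 0.0, 1.0)
    frac[coords < 0] = 0.0
    M[np.arange(n_out), i0] += (1.0 - frac).astype(DTYPE)
    M[np.arange(n_out), i1] += frac.astype(DTYPE)
    _INTERP_CACHE[key] = M
    return M


def _apply_axis(x: np.ndarray, M: np.ndarray, axis: int) -> np.ndarray:
    y = np.tensordot(M, x, axes=([1], [axis]))   # new axis first
    return np.moveaxis(y, 0, axis)


def upsample_trilinear(x: Tensor, out_shape: tuple[int, int, int]) -> Tensor:
    """Trilinear resampling of (C, D, H, W) to (C, *out_shape)."""
    Ms = [interp_matrix(x.data.shape[1 + ax], out_shape[ax]) for ax in range(3)]
    y = x.data
    for ax, M in enumerate(Ms):
        y = _apply_axis(y, M, 1 + ax)

    def bw(g):
        gx = g
        for ax, M in enumerate(Ms):
            gx = _apply_axis(gx, M.T, 1 + ax)
        x._accum(gx.astype(DTYPE))

    return _node(y.astype(DTYPE), (x,), bw)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes of (C, D, H, W).

    Stabilizes batch-size-1 volumetric training where batch statistics
    are unavailable; gamma/beta are learned per-channel affine terms.
    """
    ax = (1, 2, 3)
    mu = x.data.mean(axis=ax, keepdims=True)
    var = x.data.var(axis=ax, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    g = gamma.data[:, None, None, None]

    def bw(gr):
        n = x.data[0].size
        if beta.requires_grad:
            beta._accum(gr.sum(axis=ax))
        if gamma.requires_grad:
            gamma._accum((gr * xhat).sum(axis=ax))
        gxhat = gr * g
        # d/dx of normalization: (gxhat - mean(gxhat) - xhat*mean(gxhat*xhat)) * inv
        m1 = gxhat.mean(axis=ax, keepdims=True)
        m2 = (gxhat * xhat).mean(axis=ax, keepdims=True)
        x._accum(((gxhat - m1 - xhat * m2) * inv).astype(DTYPE))
        _ = n

    y = xhat * g + beta.data[:, None, None, None]
    return _node(y.astype(DTYPE), (x, gamma, beta), bw)


# -- parameters & optimizer --------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adaptive-moment estimation with bias correction."""

    def __init__(self, params, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
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
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
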