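"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operations the denoising network and its losses
need: broadcasting arithmetic, batched matmul, softmax, GELU, strided 2D
convolution (via im2col), nearest-neighbour upsampling, instance
normalization, reflect/symmetric padding and fixed-kernel separable 1D
filtering.  The graph is built define-by-run; ``backward`` walks it in
reverse topological order and accumulates vector-Jacobian products.

Arrays stay in whatever float width the leaves carry (float64 by default;
training feeds float32 for speed); scalar operands adopt the array
operand's dtype so graphs are never silently promoted.  Convolution is
evaluated as one channel-mixing GEMM per sample over a stacked-shift
buffer, which keeps the inner loop in BLAS.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from scipy.special import erf

__all__ = [
    "Var",
    "backward",
    "const",
    "leaf",
    "add",
    "sub",
    "mul",
    "div",
    "matmul",
    "reshape",
    "transpose",
    "softmax",
    "gelu",
    "vmean",
    "vsum",
    "conv2d",
    "upsample2x",
    "pad_end_reflect_hw",
    "crop_hw",
    "concat",
    "instance_norm",
    "conv1d_fixed",
]


class Var:
    """A node in the autodiff tape: an array plus how to back-propagate."""

    __slots__ = ("data", "grad", "_parents", "_vjp", "requires_grad")

    def __init__(
        self,
        data: np.ndarray,
        parents: Sequence["Var"] = (),
        vjp: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None,
        requires_grad: bool = False,
    ):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float64)
        elif data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._vjp = vjp
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Var(shape={self.data.shape}, requires_grad={self.requires_grad})"


def leaf(data: np.ndarray) -> Var:
    """A trainable leaf (gradients will be accumulated into ``.grad``)."""
    return Var(np.asarray(data), requires_grad=True)


def const(data) -> Var:
    return Var(np.asarray(data))


def backward(root: Var, seed: np.ndarray | None = None) -> None:
    """Back-propagate from ``root``; accumulates into ``.grad`` of leaves."""
    topo: list[Var] = []
    visited: set[int] = set()
    stack: list[tuple[Var, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited or not node.requires_grad:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    if seed is None:
        seed = np.ones_like(root.data)
    root.grad = np.asarray(seed, dtype=np.float64)
    for node in reversed(topo):
        if node._vjp is None:
            continue
        grads = node._vjp(node.grad)
        for parent, g in zip(node._parents, grads):
            if g is None or not parent.requires_grad:
                continue
            if parent.grad is None:
                parent.grad = g
            else:
                parent.grad = parent.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (adjoint of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _as_var(x) -> Var:
    return x if isinstance(x, Var) else const(x)


def _pair(a, b) -> tuple[Var, Var]:
    """Coerce operands; scalars adopt the other operand's dtype so float32
    graphs are not silently promoted back to float64."""
    if isinstance(a, Var) and not isinstance(b, Var) and np.ndim(b) == 0:
        return a, Var(np.asarray(b, dtype=a.data.dtype))
    if isinstance(b, Var) and not isinstance(a, Var) and np.ndim(a) == 0:
        return Var(np.asarray(a, dtype=b.data.dtype)), b
    return _as_var(a), _as_var(b)


# ---------------------------------------------------------------------------
# arithmetic


def add(a, b) -> Var:
    a, b = _pair(a, b)
    out = a.data + b.data
    return Var(out, (a, b), lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)))


def sub(a, b) -> Var:
    a, b = _pair(a, b)
    out = a.data - b.data
    return Var(out, (a, b), lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)))


def mul(a, b) -> Var:
    a, b = _pair(a, b)
    out = a.data * b.data
    return Var(
        out,
        (a, b),
        lambda g: (_unbroadcast(g * b.data, a.data.shape), _unbroadcast(g * a.data, b.data.shape)),
    )


def div(a, b) -> Var:
    a, b = _pair(a, b)
    out = a.data / b.data
    return Var(
        out,
        (a, b),
        lambda g: (
            _unbroadcast(g / b.data, a.data.shape),
            _unbroadcast(-g * a.data / (b.data**2), b.data.shape),
        ),
    )


def matmul(a: Var, b: Var) -> Var:
    """Batched matmul; leading batch dimensions of a and b must match."""
    if a.data.shape[:-2] != b.data.shape[:-2]:
        raise ValueError(f"matmul batch dims differ: {a.data.shape} vs {b.data.shape}")
    out = a.data @ b.data

    def vjp(g):
        return (g @ np.swapaxes(b.data, -1, -2), np.swapaxes(a.data, -1, -2) @ g)

    return Var(out, (a, b), vjp)


def reshape(a: Var, shape) -> Var:
    old = a.data.shape
    return Var(a.data.reshape(shape), (a,), lambda g: (g.reshape(old),))


def transpose(a: Var, axes) -> Var:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return Var(np.ascontiguousarray(a.data.transpose(axes)), (a,), lambda g: (g.transpose(inv),))


def concat(vars_: Sequence[Var], axis: int) -> Var:
    vars_ = [_as_var(v) for v in vars_]
    sizes = [v.data.shape[axis] for v in vars_]
    out = np.concatenate([v.data for v in vars_], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        pieces = []
        for i in range(len(vars_)):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            pieces.append(g[tuple(sl)])
        return tuple(pieces)

    return Var(out, tuple(vars_), vjp)


# ---------------------------------------------------------------------------
# nonlinearities / reductions

# plain Python floats: NumPy-2 scalars are "strong" and would promote float32
_INV_SQRT2 = float(1.0 / np.sqrt(2.0))
_INV_SQRT2PI = float(1.0 / np.sqrt(2.0 * np.pi))


def gelu(a: Var) -> Var:
    x = a.data
    phi = 0.5 * (1.0 + erf(x * _INV_SQRT2))
    out = x * phi

    def vjp(g):
        pdf = np.exp(-0.5 * x * x) * _INV_SQRT2PI
        return (g * (phi + x * pdf),)

    return Var(out, (a,), vjp)


def softmax(a: Var) -> Var:
    """Softmax over the last axis."""
    x = a.data
    m = x.max(axis=-1, keepdims=True)
    e = np.exp(x - m)
    y = e / e.sum(axis=-1, keepdims=True)

    def vjp(g):
        dot = (g * y).sum(axis=-1, keepdims=True)
        return (y * (g - dot),)

    return Var(y, (a,), vjp)


def vsum(a: Var, axes=None, keepdims: bool = False) -> Var:
    out = a.data.sum(axis=axes, keepdims=keepdims)
    shape = a.data.shape

    def vjp(g):
        if axes is None:
            return (np.broadcast_to(g, shape).copy(),)
        ax = axes if isinstance(axes, tuple) else (axes,)
        if not keepdims:
            g = np.expand_dims(g, ax)
        return (np.broadcast_to(g, shape).copy(),)

    return Var(out, (a,), vjp)


def vmean(a: Var, axes=None, keepdims: bool = False) -> Var:
    if axes is None:
        n = a.data.size
    else:
        ax = axes if isinstance(axes, tuple) else (axes,)
        n = int(np.prod([a.data.shape[i] for i in ax]))
    s = vsum(a, axes, keepdims)
    return mul(s, 1.0 / n)


# ---------------------------------------------------------------------------
# convolution and friends


def conv2d(x: Var, w: Var, b: Var, stride: int = 1) -> Var:
    """2D convolution (cross-correlation) with 'same' zero padding.

    x: [N, Cin, H, W]; w: [Cout, Cin, k, k]; b: [Cout].  For stride 2 and
    even H the output is exactly H/2.  Computed as a sum of k*k shifted
    channel-mixing matmuls, which keeps the inner loop in BLAS.
    """
    n, cin, h, wdt = x.data.shape
    cout, cin_w, k, _ = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    ho = (h + 2 * p - k) // stride + 1
    wo = (wdt + 2 * p - k) // stride + 1

    def stacked_shifts():
        xs = np.empty((n, k * k, cin, ho, wo), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                xs[:, i * k + j] = xp[:, :, i : i + (ho - 1) * stride + 1 : stride,
                                      j : j + (wo - 1) * stride + 1 : stride]
        return xs.reshape(n, k * k * cin, ho * wo)

    wm = np.ascontiguousarray(w.data.transpose(0, 2, 3, 1)).reshape(cout, k * k * cin)
    xs = stacked_shifts()
    y = np.matmul(wm, xs)  # (N, Cout, Ho*Wo), one GEMM per sample
    out = y.reshape(n, cout, ho, wo) + b.data[:, None, None]

    def vjp(g):
        g2 = g.reshape(n, cout, ho * wo)
        gb = g.sum(axis=(0, 2, 3))
        gwm = np.matmul(g2, xs.transpose(0, 2, 1)).sum(axis=0)
        gw = gwm.reshape(cout, k, k, cin).transpose(0, 3, 1, 2)
        gxs = np.matmul(wm.T, g2).reshape(n, k * k, cin, ho, wo)
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + (ho - 1) * stride + 1 : stride,
                    j : j + (wo - 1) * stride + 1 : stride] += gxs[:, i * k + j]
        gx = gxp[:, :, p : p + h, p : p + wdt]
        return (gx, np.ascontiguousarray(gw), gb)

    return Var(out, (x, w, b), vjp)


def upsample2x(x: Var) -> Var:
    """Nearest-neighbour x2 upsampling of the last two axes of [N,C,H,W]."""
    n, c, h, w = x.data.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def vjp(g):
        return (g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)),)

    return Var(out, (x,), vjp)


def _gather_last(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return x[..., idx]


def pad_end_reflect_hw(x: Var, ph: int, pw: int) -> Var:
    """Reflect-pad the trailing (H, W) axes at their high ends only."""
    if ph == 0 and pw == 0:
        return x
    *lead, h, w = x.data.shape
    idx_h = np.pad(np.arange(h), (0, ph), mode="reflect")
    idx_w = np.pad(np.arange(w), (0, pw), mode="reflect")
    out = x.data[..., idx_h, :][..., idx_w]

    def vjp(g):
        gx = np.zeros(x.data.shape, dtype=g.dtype)
        # scatter-add along W then H; padded index ranges are tiny
        gw = np.zeros((*g.shape[:-1], w), dtype=g.dtype)
        for i, src in enumerate(idx_w):
            gw[..., src] += g[..., i]
        for i, src in enumerate(idx_h):
            gx[..., src, :] += gw[..., i, :]
        return (gx,)

    return Var(out, (x,), vjp)


def crop_hw(x: Var, h: int, w: int) -> Var:
    """Keep the leading h x w window of the trailing two axes."""
    *lead, hp, wp = x.data.shape
    out = x.data[..., :h, :w]

    def vjp(g):
        gx = np.zeros(x.data.shape, dtype=g.dtype)
        gx[..., :h, :w] = g
        return (gx,)

    return Var(np.ascontiguousarray(out), (x,), vjp)


def instance_norm(x: Var, gamma: Var, beta: Var, eps: float = 1e-5,
                  stats: tuple[np.ndarray, np.ndarray] | None = None,
                  sink: list | None = None) -> Var:
    """Normalize [B, C, F, H, W] per (sample, channel) over (F, H, W).

    gamma/beta are per-channel, broadcast as [1, C, 1, 1, 1].  ``stats``
    substitutes externally calibrated (mean, variance) for the batch
    statistics (used by tiled inference); ``sink`` collects the statistics
    this call computes.
    """
    axes = (2, 3, 4)
    xd = x.data
    m = int(np.prod([xd.shape[a] for a in axes]))
    if stats is not None:
        mu, var = stats
        mu = np.asarray(mu, dtype=xd.dtype).reshape(1, -1, 1, 1, 1)
        var = np.asarray(var, dtype=xd.dtype).reshape(1, -1, 1, 1, 1)
        xc = xd - mu
        ivar = 1.0 / np.sqrt(var + eps)
        xhat = xc * ivar
        gsh = (1, -1, 1, 1, 1)
        out = gamma.data.reshape(gsh) * xhat + beta.data.reshape(gsh)

        def vjp_fixed(g):
            gg = (g * xhat).sum(axis=(0, 2, 3, 4))
            gb = g.sum(axis=(0, 2, 3, 4))
            return (g * gamma.data.reshape(gsh) * ivar, gg, gb)

        return Var(out, (x, gamma, beta), vjp_fixed)
    mu = xd.mean(axis=axes, keepdims=True)
    xc = xd - mu
    var = (xc**2).mean(axis=axes, keepdims=True)
    if sink is not None:
        sink.append((mu, var, m * xd.shape[0]))
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = xc * ivar
    gsh = (1, -1, 1, 1, 1)
    out = gamma.data.reshape(gsh) * xhat + beta.data.reshape(gsh)

    def vjp(g):
        gg = (g * xhat).sum(axis=(0, 2, 3, 4))
        gb = g.sum(axis=(0, 2, 3, 4))
        dxhat = g * gamma.data.reshape(gsh)
        dvar = (dxhat * xc).sum(axis=axes, keepdims=True) * (-0.5) * ivar**3
        dmu = -dxhat.sum(axis=axes, keepdims=True) * ivar + dvar * (-2.0 / m) * xc.sum(
            axis=axes, keepdims=True
        )
        gx = dxhat * ivar + dvar * (2.0 / m) * xc + dmu / m
        return (gx, gg, gb)

    return Var(out, (x, gamma, beta), vjp)


def conv1d_fixed(x: Var, kernel: np.ndarray, axis: int) -> Var:
    """Correlate along ``axis`` with a fixed (non-trainable) odd-length
    kernel using symmetric edge padding; output length equals input length."""
    kernel = np.asarray(kernel, dtype=x.data.dtype)
    kl = kernel.size
    if kl % 2 != 1:
        raise ValueError("conv1d_fixed kernel length must be odd")
    p = kl // 2
    xd = np.moveaxis(x.data, axis, -1)
    n = xd.shape[-1]
    idx = np.pad(np.arange(n), (p, p), mode="symmetric")
    xp = xd[..., idx]
    y = np.zeros_like(xd)
    for k in range(kl):
        y += kernel[k] * xp[..., k : k + n]
    out = np.moveaxis(y, -1, axis)

    def vjp(g):
        gm = np.moveaxis(g, axis, -1)
        gxp = np.zeros(xp.shape, dtype=g.dtype)
        for k in range(kl):
            gxp[..., k : k + n] += kernel[k] * gm
        gxd = np.zeros(xd.shape, dtype=g.dtype)
        for i, src in enumerate(idx):
            gxd[..., src] += gxp[..., i]
        return (np.moveaxis(gxd, -1, axis),)

    return Var(out, (x,), vjp)
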