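"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the fusion network and its composite loss
need: strided convolution and transposed convolution, leaky-ReLU and tanh,
elementwise arithmetic with broadcasting, an elementwise maximum across the
focal-plane axis, fixed-kernel windowed correlation (for the SSIM loss) and a
spectral mean-absolute-error term with an analytically derived gradient.

Gradients flow through a dynamically built graph of :class:`Tensor` nodes;
``Tensor.backward()`` runs a topological sweep.  Everything is float64-exact
numpy — no framework, no GPU, fully deterministic.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import fftconvolve

__all__ = [
    "Tensor", "add", "sub", "mul", "div", "neg", "scalar_mul", "scalar_add",
    "tanh", "leaky_relu", "absolute", "mean", "reshape", "max_over_axis",
    "conv2d", "conv_transpose2d", "correlate_valid", "fft_mae",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        self.grad = np.ones_like(self.data, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _node(data, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------- arithmetic

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))
    return _node(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))
    return _node(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))
    return _node(a.data * b.data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))
    return _node(a.data / b.data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        _accum(a, -g)
    return _node(-a.data, (a,), backward)


def scalar_mul(a: Tensor, s: float) -> Tensor:
    def backward(g):
        _accum(a, g * s)
    return _node(a.data * s, (a,), backward)


def scalar_add(a: Tensor, s: float) -> Tensor:
    def backward(g):
        _accum(a, g)
    return _node(a.data + s, (a,), backward)


# ------------------------------------------------------------- nonlinearities

def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)

    def backward(g):
        _accum(a, g * (1.0 - y * y))
    return _node(y, (a,), backward)


def leaky_relu(a: Tensor, negative_slope: float = 0.2) -> Tensor:
    pos = a.data > 0

    def backward(g):
        _accum(a, g * np.where(pos, 1.0, negative_slope))
    return _node(np.where(pos, a.data, negative_slope * a.data), (a,), backward)


def absolute(a: Tensor) -> Tensor:
    sign = np.sign(a.data)  # subgradient 0 at 0

    def backward(g):
        _accum(a, g * sign)
    return _node(np.abs(a.data), (a,), backward)


def mean(a: Tensor) -> Tensor:
    n = a.data.size

    def backward(g):
        _accum(a, np.full(a.data.shape, float(g) / n))
    return _node(np.asarray(a.data.mean()), (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    def backward(g):
        _accum(a, g.reshape(a.data.shape))
    return _node(a.data.reshape(shape), (a,), backward)


def max_over_axis(a: Tensor, axis: int = 0) -> Tensor:
    """Elementwise maximum reducing one axis; gradient routes to the winner.

    Ties are broken towards the lowest index along ``axis`` (argmax order),
    which makes the operation deterministic.
    """
    amax = np.argmax(a.data, axis=axis)
    y = np.max(a.data, axis=axis)

    def backward(g):
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, np.expand_dims(amax, axis),
                          np.expand_dims(g, axis), axis=axis)
        _accum(a, ga)
    return _node(y, (a,), backward)


# -------------------------------------------------------------- convolutions

def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int, pad: int) -> Tensor:
    """Strided 2-D cross-correlation, NCHW layout, weight (O, C, kh, kw)."""
    N, C, H, W = x.data.shape
    O, _, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    y = np.einsum("nchwij,ocij->nohw", win, w.data, optimize=True)
    if b is not None:
        y = y + b.data.reshape(1, O, 1, 1)
    Ho, Wo = y.shape[2], y.shape[3]

    def backward(g):
        if w.requires_grad:
            _accum(w, np.einsum("nchwij,nohw->ocij", win, g, optimize=True))
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)).reshape(b.data.shape))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + Ho * stride : stride,
                        j : j + Wo * stride : stride] += np.einsum(
                        "nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True)
            _accum(x, gxp[:, :, pad : pad + H, pad : pad + W])

    parents = (x, w) if b is None else (x, w, b)
    return _node(y, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None,
                     stride: int, pad: int) -> Tensor:
    """Transposed (fractionally strided) convolution; weight (C_in, C_out, kh, kw).

    Output size is ``(H - 1) * stride - 2 * pad + kh`` — with kernel 4,
    stride 2, pad 1 this exactly doubles the spatial dimensions.
    """
    N, Ci, H, W = x.data.shape
    _, Co, kh, kw = w.data.shape
    Ho = (H - 1) * stride - 2 * pad + kh
    Wo = (W - 1) * stride - 2 * pad + kw
    yp = np.zeros((N, Co, Ho + 2 * pad, Wo + 2 * pad), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            yp[:, :, i : i + H * stride : stride,
               j : j + W * stride : stride] += np.einsum(
                "nchw,co->nohw", x.data, w.data[:, :, i, j], optimize=True)
    y = yp[:, :, pad : pad + Ho, pad : pad + Wo]
    if b is not None:
        y = y + b.data.reshape(1, Co, 1, 1)

    def backward(g):
        gp = np.pad(g, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        win = sliding_window_view(gp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
        if x.requires_grad:
            _accum(x, np.einsum("nohwij,coij->nchw", win, w.data, optimize=True))
        if w.requires_grad:
            _accum(w, np.einsum("nchw,nohwij->coij", x.data, win, optimize=True))
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)).reshape(b.data.shape))

    parents = (x, w) if b is None else (x, w, b)
    return _node(y, parents, backward)


def correlate_valid(x: Tensor, kernel: np.ndarray) -> Tensor:
    """'Valid' windowed correlation of NCHW data with a fixed 2-D kernel.

    The kernel carries no gradient (it is the SSIM Gaussian window); the
    adjoint with respect to the input is a full convolution with the kernel.
    """
    k = np.asarray(kernel, dtype=np.float64)
    kf = k[::-1, ::-1]
    y = fftconvolve(x.data, kf[None, None], mode="valid", axes=(2, 3))

    def backward(g):
        _accum(x, fftconvolve(g, k[None, None], mode="full", axes=(2, 3)))
    return _node(y, (x,), backward)


def fft_mae(x: Tensor, target: np.ndarray, eps: float = 1e-12) -> Tensor:
    """Mean absolute value of the 2-D DFT of ``x - target`` over all bins.

    With the unnormalised DFT ``F``, ``L = mean_k |F(x - t)_k|`` and
    ``dL/dx = (H * W / M) * Re(ifft2(F / |F|))`` where ``M`` is the total
    element count — the phase of each spectral difference bin back-projected
    to pixel space.
    """
    d = x.data - target
    F = np.fft.fft2(d, axes=(-2, -1))
    mag = np.abs(F)
    M = d.size
    H, W = d.shape[-2], d.shape[-1]

    def backward(g):
        u = F / np.maximum(mag, eps)
        _accum(x, float(g) * (H * W / M) * np.real(np.fft.ifft2(u, axes=(-2, -1))))
    return _node(np.asarray(mag.sum() / M), (x,), backward)
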