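"""Minimal reverse-mode automatic differentiation over numpy arrays.

This implements exactly the operation set the segmentation networks need:
same-padded 3D convolution, strided transposed convolution, max pooling,
nearest-neighbour upsampling, ReLU, channel concatenation, residual addition,
channel softmax, centered spatial crops, and a weighted cross-entropy data
term.  Convolutions use a shift-and-matmul scheme (one GEMM per kernel tap),
which is memory-light and fast for the channel counts used here.

Arrays are float32 and carry no batch axis: activations are (C, Z, Y, X) and
training uses minibatch size 1.
"""

from __future__ import annotations

import itertools
from contextlib import contextmanager

import numpy as np

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Scalar / elementwise arithmetic used when assembling losses.
    def __add__(self, other: "Tensor") -> "Tensor":
        out = _make(self.data + other.data, (self, other))
        if out._parents:

            def bwd(g, a=self, b=other):
                if a.requires_grad or a._parents:
                    a._accum(g)
                if b.requires_grad or b._parents:
                    b._accum(g)

            out._backward = bwd
        return out

    def __mul__(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            out = _make(self.data * other.data, (self, other))
            if out._parents:

                def bwd(g, a=self, b=other):
                    if a.requires_grad or a._parents:
                        a._accum(g * b.data)
                    if b.requires_grad or b._parents:
                        b._accum(g * a.data)

                out._backward = bwd
            return out
        out = _make(self.data * float(other), (self,))
        if out._parents:

            def bwd_s(g, a=self, s=float(other)):
                a._accum(g * s)

            out._backward = bwd_s
        return out

    __rmul__ = __mul__


def _track(*parents: Tensor) -> bool:
    return _grad_enabled and any(p.requires_grad or p._parents for p in parents)


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    if _track(*parents):
        out._parents = parents
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Zero-padded shape-preserving 3D convolution with bias.

    ``x`` is (Cin, Z, Y, X); ``w`` is (Cout, Cin, kz, ky, kx) with odd kernel
    dims; ``b`` is (Cout,).
    """
    cout, cin, kz, ky, kx = w.data.shape
    _, z, y, xx = x.data.shape
    pz, py, px = kz // 2, ky // 2, kx // 2
    xp = np.pad(x.data, ((0, 0), (pz, pz), (py, py), (px, px)))
    n = z * y * xx
    out = np.zeros((cout, n), dtype=np.float32)
    taps = list(itertools.product(range(kz), range(ky), range(kx)))
    for a, bb, c in taps:
        xs = np.ascontiguousarray(xp[:, a : a + z, bb : bb + y, c : c + xx]).reshape(
            cin, n
        )
        out += w.data[:, :, a, bb, c] @ xs
    out = out.reshape(cout, z, y, xx) + b.data.reshape(-1, 1, 1, 1)
    res = _make(out, (x, w, b))
    if res._parents:

        def bwd(g):
            gm = g.reshape(cout, n)
            if b.requires_grad or b._parents:
                b._accum(g.sum(axis=(1, 2, 3)))
            need_x = x.requires_grad or x._parents
            dxp = np.zeros_like(xp) if need_x else None
            for a, bb, c in taps:
                xs = np.ascontiguousarray(
                    xp[:, a : a + z, bb : bb + y, c : c + xx]
                ).reshape(cin, n)
                if w.requires_grad or w._parents:
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[:, :, a, bb, c] += gm @ xs.T
                if need_x:
                    dxp[:, a : a + z, bb : bb + y, c : c + xx] += (
                        w.data[:, :, a, bb, c].T @ gm
                    ).reshape(cin, z, y, xx)
            if need_x:
                x._accum(
                    dxp[:, pz : pz + z, py : py + y, px : px + xx]
                    if (pz or py or px)
                    else dxp
                )

        res._backward = bwd
    return res


def conv_transpose(x: Tensor, w: Tensor, b: Tensor, factors=(1, 2, 2)) -> Tensor:
    """Transposed convolution with kernel == stride == ``factors``.

    ``w`` is (Cout, Cin, fz, fy, fx): each input voxel expands into a
    ``factors`` output block.
    """
    fz, fy, fx = factors
    cout, cin = w.data.shape[:2]
    _, z, y, xx = x.data.shape
    xm = x.data.reshape(cin, -1)
    out = np.empty((cout, z * fz, y * fy, xx * fx), dtype=np.float32)
    taps = list(itertools.product(range(fz), range(fy), range(fx)))
    for a, bb, c in taps:
        out[:, a::fz, bb::fy, c::fx] = (w.data[:, :, a, bb, c] @ xm).reshape(
            cout, z, y, xx
        )
    out += b.data.reshape(-1, 1, 1, 1)
    res = _make(out, (x, w, b))
    if res._parents:

        def bwd(g):
            if b.requires_grad or b._parents:
                b._accum(g.sum(axis=(1, 2, 3)))
            dx = None
            for a, bb, c in taps:
                gs = np.ascontiguousarray(g[:, a::fz, bb::fy, c::fx]).reshape(cout, -1)
                if w.requires_grad or w._parents:
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[:, :, a, bb, c] += gs @ xm.T
                if x.requires_grad or x._parents:
                    contrib = w.data[:, :, a, bb, c].T @ gs
                    dx = contrib if dx is None else dx + contrib
            if dx is not None:
                x._accum(dx.reshape(x.data.shape))

        res._backward = bwd
    return res


def maxpool(x: Tensor, factors=(1, 2, 2)) -> Tensor:
    """Max pooling; spatial dims must be divisible by the pool factors."""
    fz, fy, fx = factors
    c, z, y, xx = x.data.shape
    if z % fz or y % fy or xx % fx:
        raise ValueError(
            f"spatial shape {(z, y, xx)} not divisible by pool factors {factors}"
        )
    r = x.data.reshape(c, z // fz, fz, y // fy, fy, xx // fx, fx)
    r = r.transpose(0, 1, 3, 5, 2, 4, 6).reshape(
        c, z // fz, y // fy, xx // fx, fz * fy * fx
    )
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    res = _make(out, (x,))
    if res._parents:

        def bwd(g):
            dr = np.zeros(
                (c, z // fz, y // fy, xx // fx, fz * fy * fx), dtype=np.float32
            )
            np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
            dr = dr.reshape(c, z // fz, y // fy, xx // fx, fz, fy, fx)
            dr = dr.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, z, y, xx)
            x._accum(dr)

        res._backward = bwd
    return res


def upsample_nearest(x: Tensor, factors=(1, 2, 2)) -> Tensor:
    """Nearest-neighbour upsampling by integer factors."""
    fz, fy, fx = factors
    out = x.data
    if fz > 1:
        out = np.repeat(out, fz, axis=1)
    if fy > 1:
        out = np.repeat(out, fy, axis=2)
    if fx > 1:
        out = np.repeat(out, fx, axis=3)
    res = _make(np.ascontiguousarray(out), (x,))
    if res._parents:
        c, z, y, xx = x.data.shape

        def bwd(g):
            dr = g.reshape(c, z, fz, y, fy, xx, fx).sum(axis=(2, 4, 6))
            x._accum(dr)

        res._backward = bwd
    return res


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0.0)
    res = _make(out, (x,))
    if res._parents:
        mask = x.data > 0

        def bwd(g):
            x._accum(g * mask)

        res._backward = bwd
    return res


def concat_channels(tensors: list[Tensor]) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=0)
    res = _make(out, tuple(tensors))
    if res._parents:
        sizes = [t.data.shape[0] for t in tensors]

        def bwd(g):
            off = 0
            for t, s in zip(tensors, sizes):
                if t.requires_grad or t._parents:
                    t._accum(g[off : off + s])
                off += s

        res._backward = bwd
    return res


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over the channel (first) axis."""
    shifted = x.data - x.data.max(axis=0, keepdims=True)
    e = np.exp(shifted)
    p = e / e.sum(axis=0, keepdims=True)
    res = _make(p, (x,))
    if res._parents:

        def bwd(g):
            dot = (g * p).sum(axis=0, keepdims=True)
            x._accum(p * (g - dot))

        res._backward = bwd
    return res


def crop_spatial(x: Tensor, margins: tuple[int, int, int]) -> Tensor:
    """Centered crop removing ``margins`` voxels from both ends of each spatial axis."""
    mz, my, mx = margins
    if mz == my == mx == 0:
        return x
    _, z, y, xx = x.data.shape
    sl = (
        slice(None),
        slice(mz, z - mz or None),
        slice(my, y - my or None),
        slice(mx, xx - mx or None),
    )
    res = _make(np.ascontiguousarray(x.data[sl]), (x,))
    if res._parents:

        def bwd(g):
            dx = np.zeros_like(x.data)
            dx[sl] = g
            x._accum(dx)

        res._backward = bwd
    return res


def weighted_cross_entropy(
    probs: Tensor, labels: np.ndarray, weights: np.ndarray, clamp: float = 1e-12
) -> Tensor:
    """Scalar sum over voxels of ``weights * -log(max(p_true, clamp))``.

    ``probs`` is (n_classes, Z, Y, X) of per-voxel distributions, ``labels``
    an integer (Z, Y, X) array, ``weights`` a float (Z, Y, X) array treated as
    a constant.
    """
    lab = labels[None].astype(np.int64)
    pt = np.take_along_axis(probs.data, lab, axis=0)[0]
    ptc = np.maximum(pt, clamp)
    val = np.float32((weights * -np.log(ptc)).sum())
    res = _make(val, (probs,))
    if res._parents:

        def bwd(g):
            dpt = np.where(pt >= clamp, -weights / ptc, 0.0) * g
            dp = np.zeros_like(probs.data)
            np.put_along_axis(dp, lab, dpt[None].astype(np.float32), axis=0)
            probs._accum(dp)

        res._backward = bwd
    return res


def sum_squares(x: Tensor) -> Tensor:
    """Scalar sum of squared entries (L2 regularization term)."""
    res = _make(np.float32((x.data.astype(np.float64) ** 2).sum()), (x,))
    if res._parents:

        def bwd(g):
            x._accum(2.0 * g * x.data)

        res._backward = bwd
    return res
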