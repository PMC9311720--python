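"""Differentiable operators for volumetric networks.

All activations have shape ``(N, C, D, H, W)``.  Convolutions use
same-padding and are evaluated as an im2col matrix product; pooling and
trilinear upsampling both change each spatial dimension by a factor of two.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .autograd import Tensor


def _conv1x1(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    n, c, d, h, w = x.shape
    cout = weight.shape[0]
    v = d * h * w
    xf = x.data.reshape(n, c, v)
    w2d = weight.data.reshape(cout, c)
    out = np.matmul(w2d, xf).reshape(n, cout, d, h, w)
    out += bias.data.reshape(1, cout, 1, 1, 1)

    def backward(grad):
        g = grad.reshape(n, cout, v)
        if weight.requires_grad:
            weight.accumulate(np.matmul(g, xf.transpose(0, 2, 1)).sum(axis=0).reshape(weight.shape))
        if bias.requires_grad:
            bias.accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            x.accumulate(np.matmul(w2d.T, g).reshape(x.shape))

    return Tensor(out, parents=(x, weight, bias), backward_fn=backward)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor, k: int) -> Tensor:
    """Same-padded 3D convolution; ``weight`` is (Cout, Cin, k, k, k).

    Evaluated as k^3 BLAS matrix products on contiguous offset slices of
    the zero-padded, flattened volume (no patch-matrix materialisation);
    voxels whose flattened window would wrap across a row boundary are
    padding voxels, discarded when the padded result is trimmed.
    """
    if k == 1:
        return _conv1x1(x, weight, bias)
    n, c, d, h, w = x.shape
    cout = weight.shape[0]
    p = k // 2
    dp, hp, wp = d + 2 * p, h + 2 * p, w + 2 * p
    lp = dp * hp * wp
    off_max = ((k - 1) * hp + (k - 1)) * wp + (k - 1)
    lm = lp - off_max
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    xf = xp.reshape(n, c, lp)

    def offsets():
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    yield (dz * hp + dy) * wp + dx, weight.data[:, :, dz, dy, dx], (dz, dy, dx)

    outf = np.zeros((n, cout, lm), dtype=np.float32)
    for off, w_off, _ in offsets():
        outf += np.matmul(w_off, xf[:, :, off : off + lm])
    s = outf.strides
    view = as_strided(outf, shape=(n, cout, d, h, w), strides=(s[0], s[1], hp * wp * s[2], wp * s[2], s[2]))
    out = np.ascontiguousarray(view)
    out += bias.data.reshape(1, cout, 1, 1, 1)

    def backward(grad):
        # embed the gradient at the real-voxel positions of the flat layout
        gf = np.zeros((n, cout, lm), dtype=np.float32)
        gs = gf.strides
        gview = as_strided(gf, shape=(n, cout, d, h, w), strides=(gs[0], gs[1], hp * wp * gs[2], wp * gs[2], gs[2]))
        gview[:] = grad
        if bias.requires_grad:
            bias.accumulate(gf.sum(axis=(0, 2)))
        dw = np.zeros_like(weight.data) if weight.requires_grad else None
        dxf = np.zeros((n, c, lp), dtype=np.float32) if x.requires_grad else None
        for off, w_off, (dz, dy, dx) in offsets():
            sl = xf[:, :, off : off + lm]
            if dw is not None:
                dw[:, :, dz, dy, dx] = np.matmul(gf, sl.transpose(0, 2, 1)).sum(axis=0)
            if dxf is not None:
                dxf[:, :, off : off + lm] += np.matmul(w_off.T, gf)
        if dw is not None:
            weight.accumulate(dw)
        if dxf is not None:
            dxp = dxf.reshape(n, c, dp, hp, wp)
            x.accumulate(dxp[:, :, p : p + d, p : p + h, p : p + w])

    return Tensor(out, parents=(x, weight, bias), backward_fn=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(grad):
        if x.requires_grad:
            x.accumulate(grad * mask)

    return Tensor(out, parents=(x,), backward_fn=backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling; spatial dims must be even."""
    n, c, d, h, w = x.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(d, h, w)}")
    blocks = x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
    flat = blocks.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d // 2, h // 2, w // 2, 8)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(grad):
        if not x.requires_grad:
            return
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[..., None], grad[..., None], axis=-1)
        gx = (
            gflat.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(n, c, d, h, w)
        )
        x.accumulate(gx)

    return Tensor(out, parents=(x,), backward_fn=backward)


def _up_axis(a: np.ndarray, axis: int) -> np.ndarray:
    """Linear x2 upsampling along one axis (cell-centred, edges clamped)."""
    a = np.moveaxis(a, axis, 0)
    prev = np.concatenate([a[:1], a[:-1]], axis=0)
    nxt = np.concatenate([a[1:], a[-1:]], axis=0)
    out = np.empty((2 * a.shape[0],) + a.shape[1:], dtype=a.dtype)
    out[0::2] = 0.75 * a + 0.25 * prev
    out[1::2] = 0.75 * a + 0.25 * nxt
    return np.moveaxis(out, 0, axis)


def _up_axis_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, 0)
    even, odd = g[0::2], g[1::2]
    out = 0.75 * (even + odd)
    # even taps pull from the previous cell, odd taps from the next
    out[0] += 0.25 * even[0]
    out[:-1] += 0.25 * even[1:]
    out[-1] += 0.25 * odd[-1]
    out[1:] += 0.25 * odd[:-1]
    return np.moveaxis(out, 0, axis)


def upsample2(x: Tensor) -> Tensor:
    """Trilinear x2 upsampling of the three spatial dimensions."""
    out = x.data
    for axis in (2, 3, 4):
        out = _up_axis(out, axis)

    def backward(grad):
        if not x.requires_grad:
            return
        g = grad
        for axis in (4, 3, 2):
            g = _up_axis_adjoint(g, axis)
        x.accumulate(g)

    return Tensor(out, parents=(x,), backward_fn=backward)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    out = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.shape[1] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad):
        for t, g in zip(tensors, np.split(grad, splits, axis=1)):
            if t.requires_grad:
                t.accumulate(g)

    return Tensor(out, parents=tuple(tensors), backward_fn=backward)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - np.asarray(target, dtype=np.float32)
    out = np.mean(diff**2)

    def backward(grad):
        if pred.requires_grad:
            pred.accumulate(grad * 2.0 * diff / diff.size)

    return Tensor(out, parents=(pred,), backward_fn=backward)
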