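"""Minimal numpy CNN primitives with hand-written backward passes.

Everything operates on float32 NCHW batches.  Convolutions are 3x3
same-padded (plus a 1x1 head), implemented via a strided channels-first
im2col — patches laid out as (N, C*k*k, H*W) so both the forward matmul and
its adjoint run without transposing large activations; downsampling is 2x2
average pooling and upsampling is nearest-neighbour, whose backward passes
are exact adjoints.  This is deliberately a small, fully deterministic CPU
backend: given a seed, forward/backward/update sequences are
bit-reproducible.
"""

from __future__ import annotations

import numpy as np


def im2col(x: np.ndarray, k: int = 3, pad: int = 1) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patch matrix for same-size conv."""
    if k == 1 and pad == 0:
        N, C, H, W = x.shape
        return x.reshape(N, C, H * W)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    N, C, Hp, Wp = xp.shape
    H, W = Hp - k + 1, Wp - k + 1
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, (N, C, k, k, H, W), (s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return np.ascontiguousarray(cols).reshape(N, C * k * k, H * W)


def col2im(dcols: np.ndarray, xshape: tuple, k: int = 3, pad: int = 1) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patch gradients back to NCHW."""
    N, C, H, W = xshape
    if k == 1 and pad == 0:
        return dcols.reshape(N, C, H, W)
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    dc = dcols.reshape(N, C, k, k, H, W)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + H, j : j + W] += dc[:, :, i, j]
    return dxp[:, :, pad : pad + H, pad : pad + W]


class Conv2d:
    """kxk same-padded convolution; parameters W: (C_out, C_in*k*k), b: (C_out,)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.W = rng.normal(0.0, scale, size=(c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.pad = k, k // 2
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray):
        N, C, H, W = x.shape
        cols = im2col(x, self.k, self.pad)
        y = (self.W @ cols).reshape(N, self.c_out, H, W) + self.b[None, :, None, None]
        return y, (cols, x.shape)

    def backward(self, dy: np.ndarray, cache):
        cols, xshape = cache
        N, _, H, W = xshape
        dym = dy.reshape(N, self.c_out, H * W)
        dW = np.einsum("nop,nkp->ok", dym, cols, optimize=True)
        db = dym.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T, dym)
        dx = col2im(dcols, xshape, self.k, self.pad)
        return dx, dW.astype(np.float32), db.astype(np.float32)


def relu(x):
    y = np.maximum(x, 0.0)
    return y, x > 0


def relu_back(dy, mask):
    return dy * mask


def avgpool2(x):
    N, C, H, W = x.shape
    y = x.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
    return y, x.shape


def avgpool2_back(dy, xshape):
    up = np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3)
    return (up / 4.0).astype(dy.dtype)


def upsample2(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3), x.shape


def upsample2_back(dy, xshape):
    N, C, H, W = xshape
    return dy.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5))


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_per_sample(probs: np.ndarray, masks: np.ndarray):
    """Mean pixelwise CE per sample and its gradient wrt logits
    (unweighted, i.e. d(CE_i)/dlogits_i = (p - onehot)/n_pixels)."""
    N, C, H, W = probs.shape
    p_true = np.take_along_axis(
        probs, masks.astype(int)[:, None, :, :], axis=1
    )[:, 0]
    losses = -np.log(np.clip(p_true, 1e-12, None)).mean(axis=(1, 2))
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, masks.astype(int)[:, None, :, :], 1.0, axis=1)
    dlogits = (probs - onehot) / (H * W)
    return losses.astype(np.float64), dlogits
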