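"""Minimal 3D convolutional network engine in numpy.

Layers operate on single samples laid out channels-first, ``(C, D, H, W)``
float32. Each layer implements ``forward(x, train=...)`` and
``backward(grad_out)``; trainable tensors are :class:`Param` objects that
accumulate gradients across a batch, and :class:`Adam` applies the
update. Everything is plain numpy, so runs are bit-reproducible for a
fixed seed on a given platform.

Convolutions use stride 1 with same-size zero padding and are computed
as an im2col matrix product; the input gradient reuses the same machinery
with spatially flipped, channel-transposed kernels (the adjoint of a
same-padded correlation). Inference can process large volumes in slabs
along the first spatial axis to bound the im2col working set.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv3d",
    "LeakyReLU",
    "MaxPool3d",
    "Upsample3d",
    "Adam",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, D, H, W) -> (D*H*W, C*k^3) patch matrix with same zero padding."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    # (C, D, H, W, k, k, k) -> (D, H, W, C, k, k, k)
    win = win.transpose(1, 2, 3, 0, 4, 5, 6)
    d, h, w = x.shape[1:]
    return win.reshape(d * h * w, x.shape[0] * k**3)


def _conv_raw(
    x: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray | None,
    max_slab_voxels: int = 4_000_000,
) -> np.ndarray:
    """Same-padded correlation, slab-chunked along the first spatial axis."""
    out_ch, in_ch, k, _, _ = weights.shape
    d, h, w = x.shape[1:]
    wmat = weights.reshape(out_ch, in_ch * k**3)
    y = np.empty((out_ch, d, h, w), dtype=np.float32)
    slab = max(1, min(d, max_slab_voxels // max(h * w, 1)))
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    for z0 in range(0, d, slab):
        z1 = min(z0 + slab, d)
        xs = xp[:, z0 : z1 + 2 * pad]
        win = sliding_window_view(xs, (k, k, k), axis=(1, 2, 3))
        cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(
            (z1 - z0) * h * w, in_ch * k**3
        )
        ys = cols @ wmat.T
        if bias is not None:
            ys += bias
        y[:, z0:z1] = ys.reshape(z1 - z0, h, w, out_ch).transpose(3, 0, 1, 2)
    return y


class Conv3d:
    """Stride-1 3D convolution with same zero padding and odd kernel.

    Weight initialization is He-normal scaled by the fan-in, drawn from
    the generator supplied at construction.
    """

    def __init__(
        self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator
    ):
        if kernel % 2 != 1:
            raise ValueError(f"kernel edge must be odd, got {kernel}")
        fan_in = in_ch * kernel**3
        std = np.sqrt(2.0 / fan_in)
        self.kernel = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.weight = Param(
            rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel, kernel))
        )
        self.bias = Param(np.zeros(out_ch))
        self._cols: np.ndarray | None = None
        self._spatial: tuple[int, int, int] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._spatial = x.shape[1:]
            self._cols = _im2col(x, self.kernel)
            wmat = self.weight.value.reshape(self.out_ch, -1)
            y = self._cols @ wmat.T + self.bias.value
            d, h, w = self._spatial
            return np.ascontiguousarray(
                y.reshape(d, h, w, self.out_ch).transpose(3, 0, 1, 2)
            )
        return _conv_raw(x, self.weight.value, self.bias.value)

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._spatial is not None
        d, h, w = self._spatial
        gmat = g.transpose(1, 2, 3, 0).reshape(d * h * w, self.out_ch)
        self.weight.grad += (gmat.T @ self._cols).reshape(self.weight.value.shape)
        self.bias.grad += gmat.sum(axis=0)
        # adjoint: correlate g with channel-transposed, spatially flipped kernels
        w_adj = np.ascontiguousarray(
            self.weight.value.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        )
        dx = _conv_raw(g, w_adj, None)
        self._cols = None
        return dx


class LeakyReLU:
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._pos: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        pos = x > 0
        if train:
            self._pos = pos
        return np.where(pos, x, self.slope * x).astype(np.float32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._pos is not None
        dx = np.where(self._pos, g, self.slope * g).astype(np.float32)
        self._pos = None
        return dx


class MaxPool3d:
    """2x2x2 max pooling; gradients route to the argmax voxel per block."""

    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return []

    @staticmethod
    def _blocks(x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        return (
            x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(c, d // 2, h // 2, w // 2, 8)
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if any(n % 2 for n in x.shape[1:]):
            raise ValueError(f"pooling needs even spatial dims, got {x.shape[1:]}")
        xb = self._blocks(x)
        idx = xb.argmax(axis=-1)
        y = np.take_along_axis(xb, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = x.shape
        return np.ascontiguousarray(y)

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._idx is not None and self._shape is not None
        c, d, h, w = self._shape
        gb = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(gb, self._idx[..., None], g[..., None], axis=-1)
        dx = (
            gb.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, d, h, w)
        )
        self._idx = None
        self._shape = None
        return np.ascontiguousarray(dx)


def _upsample_matrix(n: int, mode: str) -> np.ndarray:
    """1D factor-2 upsampling operator as a (2n, n) matrix."""
    u = np.zeros((2 * n, n), dtype=np.float32)
    idx = np.arange(n)
    if mode == "nearest":
        u[2 * idx, idx] = 1.0
        u[2 * idx + 1, idx] = 1.0
    elif mode == "trilinear":
        # linear interpolation at output coords (i_out + 0.5)/2 - 0.5,
        # edges clamped
        left = np.clip(idx - 1, 0, n - 1)
        right = np.clip(idx + 1, 0, n - 1)
        u[2 * idx, idx] += 0.75
        u[2 * idx, left] += 0.25
        u[2 * idx + 1, idx] += 0.75
        u[2 * idx + 1, right] += 0.25
    else:
        raise ValueError(f"unknown upsample mode {mode!r}")
    return u


class Upsample3d:
    """Factor-2 upsampling along each spatial axis (nearest or trilinear).

    Implemented as a separable 1D linear operator per axis, so the
    backward pass is the exact adjoint (transposed matrix).
    """

    def __init__(self, mode: str = "nearest"):
        if mode not in ("nearest", "trilinear"):
            raise ValueError(f"unknown upsample mode {mode!r}")
        self.mode = mode
        self._mats: dict[int, np.ndarray] = {}
        self._in_shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return []

    def _mat(self, n: int) -> np.ndarray:
        if n not in self._mats:
            self._mats[n] = _upsample_matrix(n, self.mode)
        return self._mats[n]

    @staticmethod
    def _apply_axis(x: np.ndarray, m: np.ndarray, axis: int) -> np.ndarray:
        y = np.tensordot(m, x, axes=([1], [axis]))
        return np.moveaxis(y, 0, axis)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        y = x
        for axis in (1, 2, 3):
            y = self._apply_axis(y, self._mat(x.shape[axis]), axis)
        return np.ascontiguousarray(y.astype(np.float32))

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._in_shape is not None
        y = g
        for axis in (1, 2, 3):
            y = self._apply_axis(y, self._mat(self._in_shape[axis]).T, axis)
        self._in_shape = None
        return np.ascontiguousarray(y.astype(np.float32))


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(
        self,
        params: list[Param],
        beta1: float = 0.9,
        beta2: float = 0.999,
        epsilon: float = 1e-8,
    ):
        self.params = params
        self.beta1 = beta1
        self.beta2 = beta2
        self.epsilon = epsilon
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.epsilon)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
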