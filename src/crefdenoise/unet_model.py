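"""The 3D U-Net denoiser: contracting/expanding paths with skip concatenation.

The network takes a single-channel 3D density volume and returns a
denoised volume of the same shape. The contracting path applies
``depth`` blocks of (conv -> LeakyReLU -> 2x max-pool); the bottleneck is
one conv + LeakyReLU; the expanding path mirrors with ``depth`` blocks of
(2x upsample -> concatenate the matching contracting features ->
conv -> LeakyReLU -> conv -> LeakyReLU); a final single-filter
convolution produces the output. All convolutions share one kernel size
and, by default, one channel width, so the network is fully
convolutional: it is trained on patches but can denoise whole maps of
any size (padded internally to a multiple of ``2**depth``).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .grid import GeometryError, VolumeGrid
from .nn import Adam, Conv3d, LeakyReLU, MaxPool3d, Param, Upsample3d

__all__ = [
    "DenoiserConfig",
    "Denoiser",
    "build_denoiser",
    "count_parameters",
    "denoise_volume",
    "receptive_margin",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class DenoiserConfig:
    """Architecture hyperparameters of the denoiser.

    ``depth`` contracting and expanding levels, ``base_filters`` channels
    per convolution, a shared odd ``kernel`` edge, the LeakyReLU negative
    slope, the upsampling mode and the weight-initialization seed.
    """

    depth: int = 5
    base_filters: int = 16
    kernel: int = 3
    leaky_slope: float = 0.01
    upsample_mode: str = "nearest"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.base_filters < 1:
            raise ValueError(f"base_filters must be >= 1, got {self.base_filters}")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError(f"kernel edge must be a positive odd integer, got {self.kernel}")
        if self.upsample_mode not in ("nearest", "trilinear"):
            raise ValueError(f"unknown upsample mode {self.upsample_mode!r}")


class Denoiser:
    """A built (possibly trained) single-channel volume-to-volume network.

    Deterministic given fixed weights and input; weight initialization is
    fully determined by ``config.seed``.
    """

    def __init__(self, config: DenoiserConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.kernel
        b = config.base_filters
        slope = config.leaky_slope
        self.down_convs: list[Conv3d] = []
        self.down_acts: list[LeakyReLU] = []
        self.pools: list[MaxPool3d] = []
        in_ch = 1
        for _ in range(config.depth):
            self.down_convs.append(Conv3d(in_ch, b, k, rng))
            self.down_acts.append(LeakyReLU(slope))
            self.pools.append(MaxPool3d())
            in_ch = b
        self.bottleneck = Conv3d(b, b, k, rng)
        self.bottleneck_act = LeakyReLU(slope)
        self.ups: list[Upsample3d] = []
        self.up_convs_a: list[Conv3d] = []
        self.up_acts_a: list[LeakyReLU] = []
        self.up_convs_b: list[Conv3d] = []
        self.up_acts_b: list[LeakyReLU] = []
        for _ in range(config.depth):
            self.ups.append(Upsample3d(config.upsample_mode))
            self.up_convs_a.append(Conv3d(2 * b, b, k, rng))
            self.up_acts_a.append(LeakyReLU(slope))
            self.up_convs_b.append(Conv3d(b, b, k, rng))
            self.up_acts_b.append(LeakyReLU(slope))
        self.final = Conv3d(b, 1, k, rng)
        self._skip_channels = b

    # --- parameters -------------------------------------------------
    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for conv in self.down_convs:
            params += conv.params()
        params += self.bottleneck.params()
        for conv_a, conv_b in zip(self.up_convs_a, self.up_convs_b):
            params += conv_a.params()
            params += conv_b.params()
        params += self.final.params()
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # --- forward / backward -----------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[0] != 1:
            raise ValueError(f"expected (1, D, H, W) input, got {x.shape}")
        m = 2**self.config.depth
        if any(n % m for n in x.shape[1:]):
            raise ValueError(
                f"spatial dims {x.shape[1:]} must be multiples of 2^depth = {m}"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(1, D, H, W) -> (1, D, H, W); dims must divide by 2**depth."""
        x = np.asarray(x, dtype=np.float32)
        self._check_input(x)
        skips = []
        for conv, act, pool in zip(self.down_convs, self.down_acts, self.pools):
            x = act.forward(conv.forward(x, train), train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck_act.forward(self.bottleneck.forward(x, train), train)
        for i in reversed(range(self.config.depth)):
            x = self.ups[i].forward(x, train)
            x = np.concatenate([skips[i], x], axis=0)
            x = self.up_acts_a[i].forward(self.up_convs_a[i].forward(x, train), train)
            x = self.up_acts_b[i].forward(self.up_convs_b[i].forward(x, train), train)
        return self.final.forward(x, train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients; returns the input gradient."""
        g = np.asarray(g, dtype=np.float32)
        g = self.final.backward(g)
        skip_grads: list[np.ndarray | None] = [None] * self.config.depth
        b = self._skip_channels
        for i in range(self.config.depth):
            g = self.up_convs_b[i].backward(self.up_acts_b[i].backward(g))
            g = self.up_convs_a[i].backward(self.up_acts_a[i].backward(g))
            skip_grads[i] = g[:b]
            g = self.ups[i].backward(g[b:])
        g = self.bottleneck.backward(self.bottleneck_act.backward(g))
        for i in reversed(range(self.config.depth)):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.down_convs[i].backward(self.down_acts[i].backward(g))
        return g

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference without gradient caching."""
        return self.forward(x, train=False)


def build_denoiser(cfg: DenoiserConfig) -> Denoiser:
    """Construct a denoiser with seeded weight initialization.

    Two builds from the same config (including seed) have bit-identical
    initial parameters.
    """
    return Denoiser(cfg)


def count_parameters(d: Denoiser) -> int:
    """Number of trainable scalars in the network."""
    return int(sum(p.size for p in d.parameters()))


def receptive_margin(cfg: DenoiserConfig) -> int:
    """Half-width, in input voxels, of the output's receptive field.

    Voxels farther than this from a volume boundary are unaffected by
    padding, so patch-wise and whole-map inference agree there (for
    pooling-grid-aligned patch offsets).
    """
    half = cfg.kernel // 2
    margin = 0
    for level in range(cfg.depth):
        margin += half * 2**level  # contracting conv
    margin += half * 2**cfg.depth  # bottleneck
    for level in range(cfg.depth):
        margin += 2 * half * 2**level  # two expanding convs
        margin += 2**level  # interpolation reach of the upsample
    margin += half  # final conv
    return margin


def denoise_volume(d: Denoiser, v: VolumeGrid) -> VolumeGrid:
    """Denoise a whole map of any size.

    The volume is reflect-padded per axis to the next multiple of
    ``2**depth``, passed through the network without gradient caching,
    and cropped back; voxel size and origin are preserved.
    """
    m = 2**d.config.depth
    pads = []
    for n in v.shape:
        total = (-n) % m
        before = total // 2
        after = total - before
        if max(before, after) > n - 1:
            raise GeometryError(
                f"axis of size {n} is too small to reflect-pad to a multiple of {m}"
            )
        pads.append((before, after))
    x = np.pad(v.values.astype(np.float32), pads, mode="reflect")
    y = d.predict(x[None])[0]
    sl = tuple(slice(b, b + n) for (b, _), n in zip(pads, v.shape))
    return v.with_values(np.ascontiguousarray(y[sl]))


def save_checkpoint(d: Denoiser, path) -> None:
    """Serialize weights and config to a single ``.npz`` checkpoint."""
    arrays = {f"param_{i}": p.value for i, p in enumerate(d.parameters())}
    np.savez(path, __config__=json.dumps(asdict(d.config)), **arrays)


def load_checkpoint(path) -> Denoiser:
    """Rebuild a denoiser from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path, allow_pickle=False) as data:
        cfg = DenoiserConfig(**json.loads(str(data["__config__"])))
        model = Denoiser(cfg)
        params = model.parameters()
        for i, p in enumerate(params):
            stored = data[f"param_{i}"]
            if stored.shape != p.value.shape:
                raise ValueError(
                    f"checkpoint parameter {i} has shape {stored.shape}, "
                    f"model expects {p.value.shape}"
                )
            p.value[...] = stored
    return model
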