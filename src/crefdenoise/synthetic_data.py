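"""Synthetic ground truth, half-map pairs and biased "denoised" maps.

The generator emulates the statistical structure of deposited half-map
pairs at desk scale: a ground-truth density S built from Gaussian blobs,
two half-maps M_i = S + N_i with independent Gaussian noise whose
per-shell power can be pinned to a target SSNR, a soft spherical mask,
and optionally denoised-like maps D_i = S + B + a N_i with an injected
shared bias field B. Every stochastic choice flows from a single seed
through spawned substreams, so sets are reproducible end to end and the
realized per-shell spectra are recorded alongside the volumes.

It does not model cryo-EM image formation (no CTF, projection geometry
or B-factor envelope); it provides exactly the second-order statistics
that the Fourier-shell and variance-decomposition machinery assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .fourier_shell import ShellPartition, build_shell_partition
from .grid import DegenerateInputError, GeometryError, MaskVolume, VolumeGrid

__all__ = [
    "SyntheticSpec",
    "SyntheticSet",
    "make_phantom",
    "make_mask",
    "make_half_maps",
    "inject_bias",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic half-map study.

    ``ssnr`` (scalar or per-shell array) pins the per-shell
    signal-to-noise power ratio of the generated noise; when None, white
    noise with standard deviation ``noise_scale`` is used instead.
    ``bias_mode`` selects how the injected bias field B is shaped:
    ``"smooth"`` low-pass filters white noise with a Gaussian kernel of
    width ``bias_smoothness`` (in Angstrom), concentrating var_B at low
    frequency as observed for real denoisers; ``"match_signal"`` rescales
    B per shell so var_B(s) = bias_scale * var_S(s) exactly, which is the
    configuration closed-loop decomposition tests use. ``leftover_noise``
    is the factor a in D_i = S + B + a N_i.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 1.0
    n_blobs: int = 30
    blob_width: tuple[float, float] = (2.0, 6.0)  # Angstrom
    amplitude: tuple[float, float] = (0.5, 1.5)
    noise: str = "white"  # "white" | "shell"
    noise_scale: float = 1.0
    ssnr: float | np.ndarray | None = None
    bias_scale: float = 0.0
    bias_mode: str = "smooth"  # "smooth" | "match_signal"
    bias_smoothness: float = 6.0  # Angstrom
    leftover_noise: float = 1.0
    mask_radius_frac: float = 0.45
    mask_soft_edge: float = 3.0  # voxels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blob_width[0] <= 0 or self.amplitude[0] <= 0:
            raise ValueError("blob widths and amplitudes must be positive")
        if self.noise not in ("white", "shell"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.bias_mode not in ("smooth", "match_signal"):
            raise ValueError(f"unknown bias mode {self.bias_mode!r}")
        if self.noise_scale < 0 or self.bias_scale < 0:
            raise ValueError("scales must be non-negative")


@dataclass
class SyntheticSet:
    """A generated study: truth, half-maps, mask and realized spectra.

    ``spectra`` records the per-shell var_S / var_N (and var_B after
    bias injection) actually realized by the draw, for closure checks
    against the analysis modules.
    """

    truth: VolumeGrid
    m1: VolumeGrid
    m2: VolumeGrid
    mask: MaskVolume
    partition: ShellPartition
    d1: VolumeGrid | None = None
    d2: VolumeGrid | None = None
    spectra: dict = field(default_factory=dict)


def _shell_mean_power(values: np.ndarray, p: ShellPartition) -> np.ndarray:
    f = np.fft.fftn(values.astype(np.float64), norm="ortho")
    return p.shell_sum(np.abs(f) ** 2) / p.n_per_shell


def _shell_label_full(p: ShellPartition) -> np.ndarray:
    # labels for every Fourier voxel; corner voxels take the Nyquist shell
    lab = p.shell_of_voxel.copy()
    lab[lab < 0] = p.n_shells - 1
    return lab


def make_phantom(spec: SyntheticSpec) -> VolumeGrid:
    """Ground-truth density: a seeded sum of Gaussian blobs.

    Blob centers are drawn uniformly inside the central 2/3 of the box;
    widths (Angstrom) and amplitudes come from the ranges in the spec.
    ``n_blobs = 0`` gives an all-zero volume.
    """
    if min(spec.blob_width) / spec.voxel_size < 1.0:
        raise ValueError(
            "blob width below one voxel cannot be represented on this grid"
        )
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    n0, n1, n2 = spec.shape
    vol = np.zeros(spec.shape, dtype=np.float64)
    grids = np.ogrid[0:n0, 0:n1, 0:n2]
    for _ in range(spec.n_blobs):
        center = [
            rng.uniform(n / 6.0, 5.0 * n / 6.0) for n in spec.shape
        ]
        width = rng.uniform(*spec.blob_width) / spec.voxel_size  # voxels
        amp = rng.uniform(*spec.amplitude)
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        vol += amp * np.exp(-0.5 * d2 / width**2)
    return VolumeGrid(vol.astype(np.float32), voxel_size=spec.voxel_size)


def make_mask(spec: SyntheticSpec) -> MaskVolume:
    """Soft spherical mask: 1 inside ``mask_radius_frac`` of the box
    half-edge, tapering to 0 over ``mask_soft_edge`` voxels."""
    n0, n1, n2 = spec.shape
    grids = np.ogrid[0:n0, 0:n1, 0:n2]
    center = [(n - 1) / 2.0 for n in spec.shape]
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    radius = spec.mask_radius_frac * min(spec.shape)
    edge = max(spec.mask_soft_edge, 1e-6)
    mask = np.clip((radius + edge - r) / edge, 0.0, 1.0)
    return MaskVolume(mask.astype(np.float32))


def _shaped_noise(
    rng: np.random.Generator,
    target_var: np.ndarray,
    p: ShellPartition,
) -> np.ndarray:
    """Gaussian field whose per-shell mean Fourier power equals target_var."""
    white = rng.standard_normal(p.shape)
    f = np.fft.fftn(white, norm="ortho")
    lab = _shell_label_full(p)
    f *= np.sqrt(np.maximum(target_var, 0.0))[lab]
    return np.fft.ifftn(f, norm="ortho").real


def make_half_maps(truth: VolumeGrid, spec: SyntheticSpec) -> SyntheticSet:
    """Two half-maps M_i = S + N_i with independent noise realizations.

    With ``spec.ssnr`` set, the noise is Fourier-shaped per shell so that
    var_N(s) = var_S(s) / ssnr(s); the measured half-map FSC then follows
    ssnr/(1 + ssnr) in expectation. Shells where the truth has zero power
    but a finite SSNR is requested are an error (the target is
    unreachable there). With ``spec.ssnr`` None, white noise of standard
    deviation ``noise_scale`` is added. Zero noise gives M1 = M2 = S.
    """
    if truth.shape != spec.shape:
        raise GeometryError(
            f"truth shape {truth.shape} does not match spec shape {spec.shape}"
        )
    truth.require_cubic("half-map generation")
    p = build_shell_partition(truth.shape, truth.voxel_size)
    ss = np.random.SeedSequence(spec.seed)
    _, seed_n1, seed_n2, _ = ss.spawn(4)
    var_s = _shell_mean_power(truth.values, p)

    if spec.ssnr is not None:
        q = np.broadcast_to(
            np.asarray(spec.ssnr, dtype=np.float64), (p.n_shells,)
        ).copy()
        if np.any(q <= 0):
            raise ValueError("SSNR targets must be positive")
        dead = (var_s <= 0) & np.isfinite(q)
        if dead.any():
            raise DegenerateInputError(
                f"SSNR unreachable on shells with zero signal power: "
                f"{np.nonzero(dead)[0].tolist()}"
            )
        target_var_n = var_s / q
        n1 = _shaped_noise(np.random.default_rng(seed_n1), target_var_n, p)
        n2 = _shaped_noise(np.random.default_rng(seed_n2), target_var_n, p)
    elif spec.noise == "white":
        target_var_n = np.full(p.n_shells, spec.noise_scale**2)
        n1 = spec.noise_scale * np.random.default_rng(seed_n1).standard_normal(
            truth.shape
        )
        n2 = spec.noise_scale * np.random.default_rng(seed_n2).standard_normal(
            truth.shape
        )
    else:
        raise ValueError("shell-shaped noise requires an SSNR target")

    m1 = truth.with_values((truth.values + n1).astype(np.float32))
    m2 = truth.with_values((truth.values + n2).astype(np.float32))
    spectra = {
        "var_S": var_s,
        "var_N_target": target_var_n,
        "var_N1": _shell_mean_power(n1, p),
        "var_N2": _shell_mean_power(n2, p),
    }
    return SyntheticSet(
        truth=truth, m1=m1, m2=m2, mask=make_mask(spec), partition=p,
        spectra=spectra,
    )


def inject_bias(
    truth: VolumeGrid, sset: SyntheticSet, spec: SyntheticSpec
) -> SyntheticSet:
    """Denoised-like maps D_i = S + B + a N_i with a shared bias field B.

    B is drawn independently of S and the noise (its own substream of the
    spec seed). In ``smooth`` mode, B is Gaussian-filtered white noise —
    var_B concentrated at low frequency — globally scaled so its total
    variance is ``bias_scale`` times the truth's; in ``match_signal``
    mode B is Fourier-shaped so var_B(s) = bias_scale * var_S(s) on every
    shell. ``bias_scale = 0`` with a = 1 reproduces the noisy maps;
    with a = 0 it reproduces the truth (a perfect denoiser).
    """
    p = sset.partition
    ss = np.random.SeedSequence(spec.seed)
    seed_b = ss.spawn(4)[3]
    rng = np.random.default_rng(seed_b)
    var_s = sset.spectra["var_S"]
    a = float(spec.leftover_noise)

    if spec.bias_scale == 0.0:
        bias = np.zeros(truth.shape)
    elif spec.bias_mode == "match_signal":
        bias = _shaped_noise(rng, spec.bias_scale * var_s, p)
    else:
        white = rng.standard_normal(truth.shape)
        sigma_vox = spec.bias_smoothness / spec.voxel_size
        smooth = ndimage.gaussian_filter(white, sigma_vox, mode="wrap")
        sd = smooth.std()
        if sd == 0:
            raise DegenerateInputError("bias field has zero variance")
        target_sd = np.sqrt(spec.bias_scale) * truth.values.std()
        bias = smooth * (target_sd / sd)

    n1 = sset.m1.values.astype(np.float64) - truth.values
    n2 = sset.m2.values.astype(np.float64) - truth.values
    d1 = truth.with_values((truth.values + bias + a * n1).astype(np.float32))
    d2 = truth.with_values((truth.values + bias + a * n2).astype(np.float32))
    spectra = dict(sset.spectra)
    spectra["var_B"] = _shell_mean_power(bias, p)
    spectra["leftover_noise"] = a
    return replace(sset, d1=d1, d2=d2, spectra=spectra)
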