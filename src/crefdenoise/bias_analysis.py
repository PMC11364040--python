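"""Per-shell covariance machinery and the signal/noise/bias decomposition.

A noisy half-map is modelled as M_i = S + N_i and a denoised half-map as
D_i = S + B + N_i^d, where S is the common signal, N_i independent
reconstruction noise, B the (shared) bias a denoiser may introduce and
N_i^d the leftover noise after denoising. Assuming S, N_i, B and N_i^d
are mutually uncorrelated (B shared between the two denoised half-maps),
per-shell variances follow from per-shell covariances::

    var_S  = cov(M1, M2)
    var_N  = [cov(M1, M1) + cov(M2, M2)] / 2 - cov(M1, M2)
    var_B  = cov(D1, D2) - cov(D1, M2) - cov(D2, M1) + cov(M1, M2)
    var_Nd = [cov(D1, D1) + cov(D2, D2)] / 2 - cov(D1, D2)

Covariances are accumulated per frequency shell from the Hermitian
product of the Fourier coefficients. The ratios var_S/var_N (SNR) and
var_S/var_B (signal-to-bias) summarize residual noise and
denoiser-introduced bias as a function of resolution.

The decomposition fails in a recognizable way when a denoiser shrinks
both half-maps by a shared per-shell factor (signal and noise dampened
together): :func:`shrinkage_diagnostic` detects that regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fourier_shell import ShellPartition
from .grid import GeometryError, VolumeGrid

__all__ = [
    "VarianceSpectra",
    "ShrinkageDiagnostic",
    "shell_covariance",
    "decompose_noisy",
    "decompose_denoised",
    "ratio_curves",
    "shrinkage_diagnostic",
]

#: assumptions under which the four-map decomposition is exact
INDEPENDENCE_ASSUMPTIONS = (
    "S independent of N_i",
    "B independent of N_i",
    "B independent of N_i^d",
    "S independent of N_i^d",
    "N_1 independent of N_2",
    "N_1^d independent of N_2^d",
)


@dataclass
class VarianceSpectra:
    """Per-shell variance estimates from half-map covariances.

    ``var_*`` hold the clamped (non-negative) estimates used for ratio
    curves; ``raw_*`` keep the unclamped estimates, whose negative
    excursions are pure sampling noise and should be retained when
    averaging across maps.
    """

    freq_axis: np.ndarray
    raw_S: np.ndarray
    raw_N: np.ndarray
    raw_B: np.ndarray | None = None
    raw_Nd: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("raw_S", "raw_N", "raw_B", "raw_Nd"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=np.float64)
            if arr.shape != self.freq_axis.shape:
                raise ValueError(f"{name} length does not match the frequency axis")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)

    @property
    def var_S(self) -> np.ndarray:
        return np.maximum(self.raw_S, 0.0)

    @property
    def var_N(self) -> np.ndarray:
        return np.maximum(self.raw_N, 0.0)

    @property
    def var_B(self) -> np.ndarray | None:
        return None if self.raw_B is None else np.maximum(self.raw_B, 0.0)

    @property
    def var_Nd(self) -> np.ndarray | None:
        return None if self.raw_Nd is None else np.maximum(self.raw_Nd, 0.0)

    @property
    def n_shells(self) -> int:
        return len(self.freq_axis)


def shell_covariance(
    a: VolumeGrid, b: VolumeGrid, p: ShellPartition
) -> np.ndarray:
    """Per-shell covariance of two volumes' Fourier coefficients.

    For shells s >= 1, ``cov(s) = Re[(1/n_s) sum_r F_a(r) conj(F_b(r))]``
    with orthonormal FFT scaling and no mean subtraction (per-shell means
    of Fourier coefficients vanish for stationary fields). Shell 0 (DC)
    instead carries the mean-subtracted real-space covariance, which is
    the meaningful zero-frequency statistic. ``shell_covariance(x, x)``
    is the per-shell mean power of x.
    """
    a.require_same_geometry(b, "shell covariance")
    p.matches(a)
    fa = np.fft.fftn(a.values.astype(np.float64), norm="ortho")
    fb = np.fft.fftn(b.values.astype(np.float64), norm="ortho")
    sums = p.shell_sum((fa * np.conj(fb)).real)
    cov = sums / p.n_per_shell
    av = a.values.astype(np.float64)
    bv = b.values.astype(np.float64)
    cov[0] = float(np.mean((av - av.mean()) * (bv - bv.mean())))
    return cov


def decompose_noisy(
    m1: VolumeGrid, m2: VolumeGrid, p: ShellPartition
) -> tuple[np.ndarray, np.ndarray]:
    """Raw per-shell (var_S, var_N) estimates from a noisy half-map pair.

    var_S is the half-map cross-covariance; var_N the mean auto-power
    minus the cross term. Sampling noise can push either below zero in
    individual shells; values are returned unclamped.
    """
    c12 = shell_covariance(m1, m2, p)
    c11 = shell_covariance(m1, m1, p)
    c22 = shell_covariance(m2, m2, p)
    var_s = c12
    var_n = 0.5 * (c11 + c22) - c12
    return var_s, var_n


def decompose_denoised(
    m1: VolumeGrid,
    m2: VolumeGrid,
    d1: VolumeGrid,
    d2: VolumeGrid,
    p: ShellPartition,
) -> VarianceSpectra:
    """Full variance decomposition from noisy and denoised half-map pairs.

    The four-covariance combination for var_B cancels every cross term
    exactly, so an identity denoiser (D_i = M_i) returns var_B = 0 to
    machine precision and var_Nd = var_N. The independence assumptions
    the estimates rely on are recorded in the output metadata.
    """
    for v in (m2, d1, d2):
        m1.require_same_geometry(v, "variance decomposition")
    var_s, var_n = decompose_noisy(m1, m2, p)
    c_d1d2 = shell_covariance(d1, d2, p)
    c_d1m2 = shell_covariance(d1, m2, p)
    c_d2m1 = shell_covariance(d2, m1, p)
    c_m1m2 = shell_covariance(m1, m2, p)
    var_b = c_d1d2 - c_d1m2 - c_d2m1 + c_m1m2
    c_d1d1 = shell_covariance(d1, d1, p)
    c_d2d2 = shell_covariance(d2, d2, p)
    var_nd = 0.5 * (c_d1d1 + c_d2d2) - c_d1d2
    return VarianceSpectra(
        freq_axis=p.freq_axis.copy(),
        raw_S=var_s,
        raw_N=var_n,
        raw_B=var_b,
        raw_Nd=var_nd,
        metadata={"assumptions": INDEPENDENCE_ASSUMPTIONS},
    )


def ratio_curves(
    v: VarianceSpectra, floor: float = 1e-12
) -> tuple[np.ndarray, np.ndarray | None, dict[str, np.ndarray]]:
    """Signal-to-noise and signal-to-bias ratio curves.

    Returns ``(snr, signal_to_bias, flags)`` where the ratios are
    ``var_S / max(var_N, floor)`` and ``var_S / max(var_B, floor)``;
    ``flags`` marks shells whose denominator was clamped to the floor
    (ratios there are floor-limited, not measured).
    """
    if not floor > 0:
        raise ValueError("floor must be positive")
    den_n = np.maximum(v.var_N, floor)
    snr = v.var_S / den_n
    flags = {"noise_floored": v.var_N < floor}
    if v.var_B is None:
        return snr, None, flags
    den_b = np.maximum(v.var_B, floor)
    s2b = v.var_S / den_b
    flags["bias_floored"] = v.var_B < floor
    return snr, s2b, flags


@dataclass
class ShrinkageDiagnostic:
    """Per-shell detection of correlated shrinkage of both half-maps.

    ``shrinkage_1/2`` are the per-shell regression factors
    cov(D_i, M_i)/cov(M_i, M_i). A shell is flagged when both factors are
    materially below 1 and cov(D1, D2) matches the pure-shrinkage
    prediction c1*c2*cov(M1, M2) — the signature of a denoiser that
    dampens signal and noise together, violating the independence
    assumptions behind var_B/var_Nd (their estimates are unreliable on
    flagged shells).
    """

    freq_axis: np.ndarray
    shrinkage_1: np.ndarray
    shrinkage_2: np.ndarray
    flags: np.ndarray  # bool per shell
    eligible: np.ndarray  # bool: shells with enough voxels to test
    violated: bool


def shrinkage_diagnostic(
    m1: VolumeGrid,
    m2: VolumeGrid,
    d1: VolumeGrid,
    d2: VolumeGrid,
    p: ShellPartition,
    rel_tol: float = 0.1,
    shrink_max: float = 0.95,
    min_voxels: int = 100,
    min_fraction: float = 0.25,
) -> ShrinkageDiagnostic:
    """Detect the correlated-shrinkage regime on a half-map quartet.

    A shell is eligible when it holds at least ``min_voxels`` Fourier
    voxels and the half-maps correlate there (cov(M1, M2) > 0). It is
    flagged when both per-shell shrinkage factors fall below
    ``shrink_max`` and |cov(D1, D2) - c1 c2 cov(M1, M2)| is within
    ``rel_tol`` of the observed cov(D1, D2). The summary ``violated`` is
    true when at least ``min_fraction`` of eligible shells are flagged.
    """
    c_m1m2 = shell_covariance(m1, m2, p)
    c_m1m1 = shell_covariance(m1, m1, p)
    c_m2m2 = shell_covariance(m2, m2, p)
    c_d1m1 = shell_covariance(d1, m1, p)
    c_d2m2 = shell_covariance(d2, m2, p)
    c_d1d2 = shell_covariance(d1, d2, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        c1 = np.where(c_m1m1 > 0, c_d1m1 / np.maximum(c_m1m1, 1e-300), 0.0)
        c2 = np.where(c_m2m2 > 0, c_d2m2 / np.maximum(c_m2m2, 1e-300), 0.0)
    predicted = c1 * c2 * c_m1m2
    eligible = (p.n_per_shell >= min_voxels) & (c_m1m2 > 0)
    scale = np.maximum(np.abs(c_d1d2), 1e-300)
    close = np.abs(c_d1d2 - predicted) <= rel_tol * scale
    shrunk = (c1 < shrink_max) & (c2 < shrink_max) & (c1 > 0) & (c2 > 0)
    flags = eligible & close & shrunk
    n_eligible = int(eligible.sum())
    violated = bool(
        n_eligible > 0 and flags.sum() >= min_fraction * n_eligible
    )
    return ShrinkageDiagnostic(
        freq_axis=p.freq_axis.copy(),
        shrinkage_1=c1,
        shrinkage_2=c2,
        flags=flags,
        eligible=eligible,
        violated=violated,
    )
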