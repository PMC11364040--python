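"""Scalar map-quality metrics: FSC-threshold resolution and curve RMSE.

The resolution of a map pair is read off an FSC curve as the reciprocal
of the frequency where the curve first falls below a threshold (0.143
for gold-standard half-map resolution — the value at which Cref reaches
0.5 — or 0.5 when comparing a map against a reference). The match
between a denoised map's FSC_FD and the theoretical Cref is summarized
as the RMSE of the *squared* curves, which keeps the statistic stable
where the curves approach zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier_shell import (
    CrefCurve,
    FSCCurve,
    ShellPartition,
    compute_fsc,
)
from .grid import MaskVolume, VolumeGrid

__all__ = [
    "ResolutionEstimate",
    "fsc_threshold_resolution",
    "rmse_fsc_to_cref",
    "fsc_threshold_change",
]


@dataclass(frozen=True)
class ResolutionEstimate:
    """An FSC-threshold crossing.

    ``crossed`` is False when the curve never falls below the threshold;
    the estimate is then pinned at the Nyquist limit (the best resolution
    the grid can express, 2x the voxel size when frequencies are in
    1/Angstrom).
    """

    threshold: float
    crossing_freq: float  # 1/Angstrom
    resolution: float  # Angstrom
    crossed: bool


def fsc_threshold_resolution(c: FSCCurve, threshold: float) -> ResolutionEstimate:
    """Resolution at the first downward threshold crossing of an FSC curve.

    Scans outward from shell 1 (DC excluded) and linearly interpolates
    the crossing frequency between the first pair of consecutive shells
    that straddle the threshold; re-risings after the first crossing are
    ignored. A curve that starts below the threshold at shell 1 crosses
    there; a curve that never falls below it returns the Nyquist
    sentinel with ``crossed=False``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if len(c) < 2:
        raise ValueError("curve must have at least 2 shells")
    vals = c.values
    freqs = c.freq_axis
    if vals[1] < threshold:
        f = freqs[1]
        return ResolutionEstimate(threshold, float(f), float(1.0 / f), True)
    for s in range(1, len(vals) - 1):
        if vals[s] >= threshold and vals[s + 1] < threshold:
            t = (vals[s] - threshold) / (vals[s] - vals[s + 1])
            f = freqs[s] + t * (freqs[s + 1] - freqs[s])
            return ResolutionEstimate(threshold, float(f), float(1.0 / f), True)
    f_nyq = float(freqs[-1])
    return ResolutionEstimate(threshold, f_nyq, 1.0 / f_nyq, False)


def rmse_fsc_to_cref(fsc_fd: FSCCurve, cref: CrefCurve) -> float:
    """RMSE between the squared FSC_FD and squared Cref curves.

    sqrt(mean over shells 1..N/2 of (FSC_FD^2 - Cref^2)^2). Squaring
    before differencing keeps the metric numerically stable; identical
    curves give 0 and a unit offset of the squares gives 1.
    """
    if len(fsc_fd) != len(cref):
        raise ValueError(
            f"curve length mismatch: {len(fsc_fd)} vs {len(cref)}"
        )
    d = fsc_fd.values[1:] ** 2 - cref.values[1:] ** 2
    return float(np.sqrt(np.mean(d**2)))


def fsc_threshold_change(
    denoised_half: VolumeGrid,
    other_half: VolumeGrid,
    m1: VolumeGrid,
    m2: VolumeGrid,
    p: ShellPartition,
    mask: MaskVolume | None = None,
    threshold: float = 0.5,
) -> float:
    """Change in FSC-threshold resolution from denoising one half-map.

    Returns resolution(denoised_half, other_half) minus
    resolution(m1, m2) in Angstrom; negative values mean the denoised
    pair crosses the threshold at higher frequency (improved). Masks are
    applied to every input before the FSC is computed.
    """
    if mask is not None:
        denoised_half = mask.apply(denoised_half)
        other_half = mask.apply(other_half)
        m1 = mask.apply(m1)
        m2 = mask.apply(m2)
    res_den = fsc_threshold_resolution(
        compute_fsc(denoised_half, other_half, p), threshold
    )
    res_noisy = fsc_threshold_resolution(compute_fsc(m1, m2, p), threshold)
    return res_den.resolution - res_noisy.resolution
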