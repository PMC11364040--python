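"""Core volume containers and error types.

A cryo-EM density map is represented as a :class:`VolumeGrid`: a 3D
real-valued scalar field on a regular grid with an isotropic voxel size
(in Angstrom) and a real-space origin. Half-maps, denoised maps,
ground-truth phantoms and masks all live on such grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeGrid",
    "MaskVolume",
    "GeometryError",
    "DegenerateInputError",
]

#: smallest supported edge length, in voxels
MIN_EDGE = 8


class GeometryError(ValueError):
    """Raised when volume shapes, voxel sizes or masks are incompatible."""


class DegenerateInputError(ValueError):
    """Raised for inputs with no usable signal (all-zero maps, zero variance)."""


@dataclass
class VolumeGrid:
    """A 3D density map with voxel size and origin.

    Parameters
    ----------
    values :
        3D array of finite real values. Stored as float32 unless the
        input is already a floating dtype.
    voxel_size :
        Isotropic voxel edge length in Angstrom.
    origin :
        Real-space origin in Angstrom (MRC header convention, passed
        through untouched by the I/O layer).
    """

    values: np.ndarray
    voxel_size: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise GeometryError(f"expected a 3D volume, got ndim={arr.ndim}")
        if any(n < MIN_EDGE for n in arr.shape):
            raise GeometryError(
                f"every axis must have at least {MIN_EDGE} voxels, got {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume contains non-finite values")
        if not self.voxel_size > 0:
            raise GeometryError(f"voxel size must be positive, got {self.voxel_size}")
        self.values = arr
        self.origin = tuple(float(x) for x in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def is_cubic(self) -> bool:
        n0, n1, n2 = self.values.shape
        return n0 == n1 == n2

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        """A new grid with the same geometry but different values."""
        return VolumeGrid(values, voxel_size=self.voxel_size, origin=self.origin)

    def require_cubic(self, what: str = "operation") -> int:
        """Return the cube edge, or raise naming the offending axes."""
        n0, n1, n2 = self.values.shape
        if not (n0 == n1 == n2):
            raise GeometryError(
                f"{what} requires a cubic volume; axes have sizes "
                f"({n0}, {n1}, {n2})"
            )
        return n0

    def require_same_geometry(self, other: "VolumeGrid", what: str = "operation") -> None:
        if self.shape != other.shape:
            raise GeometryError(
                f"{what}: shape mismatch {self.shape} vs {other.shape}"
            )
        if not np.isclose(self.voxel_size, other.voxel_size, rtol=1e-4):
            raise GeometryError(
                f"{what}: voxel size mismatch {self.voxel_size} vs {other.voxel_size}"
            )


@dataclass
class MaskVolume:
    """A [0, 1]-valued mask on the same grid as the maps it selects.

    Binary masks mark the particle region; soft masks taper the edge.
    Masks are applied by voxelwise multiplication and are never
    resampled — mismatched geometry is an error.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float32)
        if arr.ndim != 3:
            raise GeometryError(f"mask must be 3D, got ndim={arr.ndim}")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("mask values must lie in [0, 1]")
        if not (arr > 0).any():
            raise DegenerateInputError("mask has no positive voxels")
        self.values = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def apply(self, v: VolumeGrid) -> VolumeGrid:
        if self.shape != v.shape:
            raise GeometryError(
                f"mask shape {self.shape} does not match map shape {v.shape}; "
                "masks are never resampled"
            )
        return v.with_values(v.values * self.values)
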