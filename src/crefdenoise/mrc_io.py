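"""MRC/CCP4 volume I/O and curve/spectra table serialization.

Volumes are read and written through gemmi. Reading normalizes the axis
order to the canonical (X, Y, Z) convention (logging a note when the
file was permuted), converts data to float32 and checks voxel-size
isotropy; writing emits mode-2 (float32) maps with recomputed header
statistics. The MRC origin words are passed through untouched in both
directions. Curves and variance spectra are exchanged as tab-separated
tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .grid import GeometryError, VolumeGrid

__all__ = [
    "MapHeaderInfo",
    "read_mrc",
    "write_mrc",
    "read_map_header",
    "write_curve_tsv",
    "read_curve_tsv",
    "write_spectra_tsv",
]

logger = logging.getLogger(__name__)

#: relative tolerance on voxel-size anisotropy before a warning is raised
ANISOTROPY_RTOL = 1e-3


@dataclass(frozen=True)
class MapHeaderInfo:
    """Selected MRC header fields of a map file."""

    mode: int
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]
    axis_order: tuple[int, int, int]
    dmin: float
    dmax: float
    dmean: float


def read_map_header(path: str | Path) -> MapHeaderInfo:
    """Header fields as stored in the file (no axis normalization)."""
    m = gemmi.read_ccp4_map(str(path))
    return MapHeaderInfo(
        mode=m.header_i32(4),
        voxel_size=tuple(m.grid.spacing),
        origin=tuple(m.header_float(w) for w in (50, 51, 52)),
        axis_order=tuple(m.header_i32(w) for w in (17, 18, 19)),
        dmin=m.header_float(20),
        dmax=m.header_float(21),
        dmean=m.header_float(22),
    )


def read_mrc(path: str | Path) -> VolumeGrid:
    """Read an MRC/CCP4 volume as a canonical float32 :class:`VolumeGrid`.

    Files stored with a permuted axis order are reordered to (X, Y, Z)
    with a logged note. Anisotropic voxel sizes beyond a small tolerance
    produce a warning and the mean spacing is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such map file: {path}")
    m = gemmi.read_ccp4_map(str(path))
    axis_order = tuple(m.header_i32(w) for w in (17, 18, 19))
    origin = tuple(float(m.header_float(w)) for w in (50, 51, 52))
    if axis_order != (1, 2, 3):
        logger.info(
            "map %s stored with permuted axis order %s; normalizing to (1, 2, 3)",
            path.name,
            axis_order,
        )
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(m.grid, copy=True).astype(np.float32)
    spacing = np.array(m.grid.spacing, dtype=np.float64)
    if spacing.max() <= 0:
        raise ValueError(f"map {path} has non-positive voxel size {tuple(spacing)}")
    if np.ptp(spacing) > ANISOTROPY_RTOL * spacing.mean():
        logger.warning(
            "map %s has anisotropic voxel sizes %s; using the mean",
            path.name,
            tuple(spacing),
        )
    return VolumeGrid(values, voxel_size=float(spacing.mean()), origin=origin)


def write_mrc(v: VolumeGrid, path: str | Path) -> None:
    """Write a volume as a mode-2 (float32) MRC map.

    The unit cell encodes the isotropic voxel size, header statistics
    (min/max/mean) are recomputed from the data, and the volume's origin
    is stored in the MRC origin words.
    """
    values = np.ascontiguousarray(v.values, dtype=np.float32)
    if not np.all(np.isfinite(values)):
        raise ValueError("refusing to write a volume with non-finite values")
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(values)
    n0, n1, n2 = v.shape
    m.grid.unit_cell = gemmi.UnitCell(
        n0 * v.voxel_size, n1 * v.voxel_size, n2 * v.voxel_size, 90.0, 90.0, 90.0
    )
    m.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m.update_ccp4_header()
    for w, val in zip((50, 51, 52), v.origin):
        m.set_header_float(w, float(val))
    m.write_ccp4_map(str(path))


def write_curve_tsv(
    path: str | Path,
    freq_axis: np.ndarray,
    values: np.ndarray,
    value_name: str = "value",
) -> None:
    """Write a per-shell curve as a TSV table.

    Columns: shell_index, frequency_invA, resolution_A (reciprocal
    frequency; ``inf`` at DC) and the curve value.
    """
    freq = np.asarray(freq_axis, dtype=np.float64)
    with np.errstate(divide="ignore"):
        resolution = np.where(freq > 0, 1.0 / np.maximum(freq, 1e-300), np.inf)
    pd.DataFrame(
        {
            "shell_index": np.arange(len(freq)),
            "frequency_invA": freq,
            "resolution_A": resolution,
            value_name: np.asarray(values, dtype=np.float64),
        }
    ).to_csv(path, sep="\t", index=False)


def read_curve_tsv(path: str | Path) -> pd.DataFrame:
    """Read a curve table written by :func:`write_curve_tsv`."""
    df = pd.read_csv(path, sep="\t")
    required = {"shell_index", "frequency_invA"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"curve table {path} is missing columns {sorted(missing)}")
    return df


def write_spectra_tsv(path: str | Path, spectra, snr=None, s2b=None, flags=None) -> None:
    """Write a :class:`~crefdenoise.bias_analysis.VarianceSpectra` table.

    Columns: shell, frequency, the four variance components (raw), the
    ratio curves and the clamp flags.
    """
    freq = spectra.freq_axis
    table: dict = {
        "shell_index": np.arange(len(freq)),
        "frequency_invA": freq,
        "var_S": spectra.raw_S,
        "var_N": spectra.raw_N,
    }
    if spectra.raw_B is not None:
        table["var_B"] = spectra.raw_B
    if spectra.raw_Nd is not None:
        table["var_Nd"] = spectra.raw_Nd
    if snr is not None:
        table["snr"] = snr
    if s2b is not None:
        table["signal_to_bias"] = s2b
    if flags:
        for name, arr in flags.items():
            table[f"flag_{name}"] = np.asarray(arr, dtype=int)
    pd.DataFrame(table).to_csv(path, sep="\t", index=False)
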