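"""Data preparation: masking, standardization, patch tiling and splitting.

Half-map pairs are masked and standardized (whole-map mean 0, standard
deviation 1), then cut into non-overlapping cubic patches on a regular
grid; a final partial window on any axis is shifted back to end flush
with the volume boundary, so every patch is full-size. Patch windows
whose mask content is identically zero are dropped. Train/test splitting
happens at the source-map level so no map contributes patches to both
sides of the split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grid import DegenerateInputError, GeometryError, MaskVolume, VolumeGrid

__all__ = [
    "PatchPair",
    "standardize",
    "tile_patches",
    "split_by_map",
    "save_patch_dataset",
    "load_patch_dataset",
]

DEFAULT_PATCH_EDGE = 96


@dataclass
class PatchPair:
    """Matched cubic sub-volumes cut from two half-maps at one offset."""

    p1: np.ndarray
    p2: np.ndarray
    source_id: str
    offset: tuple[int, int, int]  # 0-based corner in the source map
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.p1.shape != self.p2.shape:
            raise GeometryError(
                f"patch shapes differ: {self.p1.shape} vs {self.p2.shape}"
            )
        e = self.p1.shape[0]
        if self.p1.shape != (e, e, e):
            raise GeometryError(f"patches must be cubic, got {self.p1.shape}")

    @property
    def edge(self) -> int:
        return self.p1.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return 0.5 * (self.p1 + self.p2)


def standardize(
    v: VolumeGrid,
    m: MaskVolume | None = None,
    stats_within_mask: bool = False,
    return_stats: bool = False,
):
    """Mask (optional) and standardize a map to mean 0, std 1.

    The statistics are computed over all voxels of the masked volume —
    zeros outside the mask included — matching a masking-then-
    standardization sequence; ``stats_within_mask`` restricts them to
    voxels where the mask is positive instead. Standardization is
    idempotent, and a volume with zero variance after masking is
    rejected.
    """
    values = v.values
    if m is not None:
        if m.shape != v.shape:
            raise GeometryError(
                f"mask shape {m.shape} does not match map shape {v.shape}"
            )
        values = values * m.values
    if stats_within_mask and m is not None:
        sel = values[m.values > 0]
        mean = float(sel.mean())
        std = float(sel.std())
    else:
        mean = float(values.mean())
        std = float(values.std())
    if std == 0.0:
        raise DegenerateInputError("zero variance after masking; cannot standardize")
    out = v.with_values(((values - mean) / std).astype(np.float32))
    if return_stats:
        return out, {"mean": mean, "std": std}
    return out


def _axis_offsets(size: int, edge: int) -> list[int]:
    if edge > size:
        raise GeometryError(f"patch edge {edge} exceeds axis size {size}")
    offsets = []
    for start in range(0, size, edge):
        offsets.append(min(start, size - edge))
    return sorted(set(offsets))


def tile_patches(
    m1: VolumeGrid,
    m2: VolumeGrid,
    mask: MaskVolume,
    edge: int = DEFAULT_PATCH_EDGE,
    source_id: str = "",
) -> list[PatchPair]:
    """Cut both half-maps into matched cubic patches, dropping empty ones.

    Windows form a non-overlapping grid starting at the origin; a final
    partial window is shifted back to end flush with the boundary (full
    size, possibly overlapping its neighbor). Windows whose mask content
    is identically zero are removed; both half-maps are cut at identical
    offsets.
    """
    m1.require_same_geometry(m2, "patch tiling")
    if mask.shape != m1.shape:
        raise GeometryError(
            f"mask shape {mask.shape} does not match map shape {m1.shape}"
        )
    axes_offsets = [_axis_offsets(n, edge) for n in m1.shape]
    pairs: list[PatchPair] = []
    for o0 in axes_offsets[0]:
        for o1 in axes_offsets[1]:
            for o2 in axes_offsets[2]:
                window = (
                    slice(o0, o0 + edge),
                    slice(o1, o1 + edge),
                    slice(o2, o2 + edge),
                )
                if not (mask.values[window] > 0).any():
                    continue
                pairs.append(
                    PatchPair(
                        p1=np.ascontiguousarray(m1.values[window]),
                        p2=np.ascontiguousarray(m2.values[window]),
                        source_id=source_id,
                        offset=(o0, o1, o2),
                        voxel_size=m1.voxel_size,
                    )
                )
    return pairs


def split_by_map(
    entries: list[str], test_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Seeded map-level train/test split.

    Returns ``(train_ids, test_ids)`` with ``len(test_ids) =
    round(test_fraction * len(entries))`` and the two sides disjoint, so
    no source map contributes patches to both. The same seed always
    yields the same split.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test fraction must be in (0, 1), got {test_fraction}")
    if len(entries) < 2:
        raise ValueError("need at least 2 entries to split")
    if len(set(entries)) != len(entries):
        raise ValueError("entry ids must be unique")
    rng = np.random.default_rng(seed)
    shuffled = list(entries)
    rng.shuffle(shuffled)
    n_test = int(round(test_fraction * len(entries)))
    n_test = min(max(n_test, 1), len(entries) - 1)
    test_ids = shuffled[:n_test]
    train_ids = shuffled[n_test:]
    return train_ids, test_ids


def save_patch_dataset(
    pairs: list[PatchPair], out_dir: str | Path, extra_manifest: dict | None = None
) -> Path:
    """Persist patch pairs as one ``.npz`` archive per source entry.

    The manifest (JSON) records per entry the offsets, edge and voxel
    size; ``extra_manifest`` entries (e.g. standardization stats, split
    assignment) are merged in at the top level.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_source: dict[str, list[PatchPair]] = {}
    for pair in pairs:
        by_source.setdefault(pair.source_id or "unnamed", []).append(pair)
    manifest: dict = {"entries": {}, "n_pairs": len(pairs)}
    if extra_manifest:
        manifest.update(extra_manifest)
    for source_id, group in by_source.items():
        fname = f"{source_id}.npz"
        np.savez(
            out_dir / fname,
            p1=np.stack([g.p1 for g in group]),
            p2=np.stack([g.p2 for g in group]),
            offsets=np.array([g.offset for g in group], dtype=np.int64),
        )
        manifest["entries"][source_id] = {
            "file": fname,
            "n_patches": len(group),
            "edge": group[0].edge,
            "voxel_size": group[0].voxel_size,
            "offsets": [list(g.offset) for g in group],
        }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir / "manifest.json"


def load_patch_dataset(
    dataset_dir: str | Path, source_ids: list[str] | None = None
) -> list[PatchPair]:
    """Load patch pairs written by :func:`save_patch_dataset`.

    ``source_ids`` restricts loading to a subset of entries (e.g. the
    train side of a split).
    """
    dataset_dir = Path(dataset_dir)
    manifest = json.loads((dataset_dir / "manifest.json").read_text())
    pairs: list[PatchPair] = []
    for source_id, info in manifest["entries"].items():
        if source_ids is not None and source_id not in source_ids:
            continue
        with np.load(dataset_dir / info["file"]) as data:
            p1s, p2s, offsets = data["p1"], data["p2"], data["offsets"]
        for p1, p2, off in zip(p1s, p2s, offsets):
            pairs.append(
                PatchPair(
                    p1=p1,
                    p2=p2,
                    source_id=source_id,
                    offset=tuple(int(x) for x in off),
                    voxel_size=float(info["voxel_size"]),
                )
            )
    return pairs
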