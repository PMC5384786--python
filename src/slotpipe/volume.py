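"""Isotropic 3D volumes and their on-disk representation.

A :class:`Volume` is the common currency of the pipeline: phantom emission
maps, absorption maps, and reconstructed tomograms are all isotropic scalar
grids indexed ``(z, y, x)`` with a physical voxel size in micrometres.
Volumes are written as multi-page TIFF (one page per z-slice) with a JSON
sidecar carrying the physical metadata, so every artifact on disk can be
read back losslessly by the package itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Volume", "save_volume", "load_volume", "sidecar_path"]


@dataclass
class Volume:
    """Isotropic scalar 3D grid.

    Parameters
    ----------
    data
        Array of shape ``(nz, ny, nx)``. Stored as float32 unless the
        caller supplies another dtype explicitly (masks use uint8).
    voxel_size_um
        Edge length of the cubic voxel in micrometres. Must be positive.
    meta
        Free-form metadata recorded in the JSON sidecar (channel name,
        stage provenance, ...).
    """

    data: np.ndarray
    voxel_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def center_voxel(self) -> np.ndarray:
        """Grid center in fractional voxel indices, ``(z, y, x)``."""
        return (np.asarray(self.shape, dtype=float) - 1.0) / 2.0

    def voxel_to_um(self, idx) -> np.ndarray:
        """Convert voxel indices to physical coordinates (μm, grid-centered)."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return (idx - self.center_voxel()) * self.voxel_size_um

    def um_to_voxel(self, pts_um) -> np.ndarray:
        """Convert grid-centered physical coordinates (μm) to fractional voxel indices."""
        pts_um = np.atleast_2d(np.asarray(pts_um, dtype=float))
        return pts_um / self.voxel_size_um + self.center_voxel()

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size_um, dict(self.meta))


def sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def save_volume(vol: Volume, path) -> Path:
    """Write a volume as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = vol.data
    if data.dtype not in (np.uint8, np.uint16):
        data = data.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {"voxel_size_um": float(vol.voxel_size_um), "shape": list(vol.shape)}
    meta.update(vol.meta)
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def load_volume(path) -> Volume:
    """Read a volume written by :func:`save_volume`."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:  # single-page edge case
        data = data[None]
    meta = json.loads(sidecar_path(path).read_text())
    voxel = float(meta.pop("voxel_size_um"))
    meta.pop("shape", None)
    return Volume(data, voxel, meta)
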