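"""Parallel-beam forward model of SLOT acquisition.

The scan optics displace the laser beam parallel to itself, so each
projection pixel is a line integral through the sample: fluorescence along
the illumination direction (emission is collected orthogonally but, in an
index-matched cleared sample, without further attenuation), and extinction
as the Beer–Lambert optical density ``−ln(I/I₀)`` measured by the photo
diode behind the cuvette. The sample rotates about the detector-vertical
axis (volume z); we implement rotation on the volume (slice-wise, linear
interpolation, zeros outside the grid) rather than on rays.

Angle convention: positive angles rotate the sample counter-clockwise when
looking down +z, with angle 0 illuminating along +x. The convention is
recorded in the stack metadata. In array terms the projection at angle θ is
``rotate(volume, −θ, axes=(y, x)).sum(axis=x) · voxel_size``, which places
a voxel at centered coordinates (y, x) at detector position
``t = y·cosθ + x·sinθ`` — the relation the back projector inverts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .phantom import InstrumentConfig
from .volume import Volume, sidecar_path

__all__ = [
    "ProjectionStack",
    "project_fluorescence",
    "project_extinction",
    "save_stack",
    "load_stack",
]


@dataclass
class ProjectionStack:
    """Ordered 2D projections over a rotation series.

    ``images`` has shape ``(n_angles, detector_y, detector_x)`` where the
    detector-vertical axis (rows) coincides with the volume z axis.
    """

    images: np.ndarray
    angles_deg: np.ndarray
    pixel_pitch_um: float
    channel: dict = field(default_factory=dict)
    rotation_axis: str = "detector-vertical"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n_angles, ny, nx) array")
        if len(self.images) != len(self.angles_deg):
            raise ValueError("len(images) must equal len(angles_deg)")
        if len(self.angles_deg) > 1 and not np.all(np.diff(self.angles_deg) > 0):
            raise ValueError("angles_deg must be strictly increasing")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be > 0")

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)


def _rotate_vol(data: np.ndarray, angle_deg: float) -> np.ndarray:
    """Slice-wise in-plane rotation about the z axis (linear interp, cval 0)."""
    if angle_deg % 360.0 == 0.0:
        return data
    return ndimage.rotate(
        data, angle_deg, axes=(1, 2), reshape=False, order=1, mode="constant", cval=0.0
    )


def _project(vol: Volume, cfg: InstrumentConfig, channel: dict) -> ProjectionStack:
    angles = cfg.angles_deg()
    data = vol.data.astype(np.float32, copy=False)
    out = np.empty((len(angles), data.shape[0], data.shape[1]), dtype=np.float32)
    for i, ang in enumerate(angles):
        rotated = _rotate_vol(data, -ang)
        out[i] = rotated.sum(axis=2) * vol.voxel_size_um
    return ProjectionStack(
        images=out,
        angles_deg=angles,
        pixel_pitch_um=vol.voxel_size_um,
        channel=channel,
    )


def project_fluorescence(vol: Volume, cfg: InstrumentConfig) -> ProjectionStack:
    """Fluorescence rotation series: line integrals of the emission map.

    Output pixels carry intensity·μm. The detector grid matches the volume
    grid (detector rows = z slices, pitch = voxel size); ``cfg`` supplies
    the angular sampling.
    """
    channel = {"kind": "fluorescence", **{k: v for k, v in vol.meta.items()}}
    return _project(vol, cfg, channel)


def project_extinction(absorption: Volume, cfg: InstrumentConfig) -> ProjectionStack:
    """Extinction rotation series: Beer–Lambert optical density sinograms.

    Input is the absorption-coefficient map (per μm); each output pixel is
    the line integral ``−ln(I/I₀)``, already log-converted so filtered back
    projection applies directly.
    """
    if np.any(absorption.data < 0):
        raise ValueError("absorption coefficients must be non-negative")
    channel = {"kind": "extinction", **{k: v for k, v in absorption.meta.items()}}
    return _project(absorption, cfg, channel)


# --------------------------------------------------------------------------- #
# I/O: multi-page TIFF (one page per angle) + JSON sidecar


def save_stack(stack: ProjectionStack, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.images.astype(np.float32), photometric="minisblack")
    meta = {
        "angles_deg": [float(a) for a in stack.angles_deg],
        "pixel_pitch_um": float(stack.pixel_pitch_um),
        "channel": stack.channel,
        "rotation_axis": stack.rotation_axis,
        "angle_convention": "ccw looking down +z; angle 0 illuminates along +x",
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def load_stack(path) -> ProjectionStack:
    path = Path(path)
    images = tifffile.imread(path)
    if images.ndim == 2:
        images = images[None]
    meta = json.loads(sidecar_path(path).read_text())
    return ProjectionStack(
        images=images,
        angles_deg=np.asarray(meta["angles_deg"]),
        pixel_pitch_um=meta["pixel_pitch_um"],
        channel=meta.get("channel", {}),
        rotation_axis=meta.get("rotation_axis", "detector-vertical"),
    )
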