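"""Synthetic cochlea phantom with exactly known geometry.

The labeled neurofilament (spiral ganglion somata in Rosenthal's canal)
is modelled as a tube around a conical helix: the in-plane radius shrinks
linearly with turn angle from base to apex while z rises linearly. A row of
point-like bright spots offset laterally from the tube stands in for the
otoferlin-labeled inner hair cells, and an enclosing autofluorescent
ellipsoidal shell mimics the decalcified bony capsule. A companion
absorption map (shell + interior soft tissue) provides the extinction
contrast used for inter-channel registration.

Everything downstream is validated against the analytic ground truth
carried by :class:`GroundTruth`: the densely sampled centerline, its arc
length, and its per-point curvature radius from the space-curve formula
``κ = |r' × r''| / |r'|³``. For a constant-radius helix with in-plane
radius ``a`` and rise per radian ``c`` this reduces to the closed form
``radius = (a² + c²)/a``.

The default geometry uses a deliberately steep pitch so that the
three-dimensional curvature radius is *smaller* at the wide basal turn than
at the narrow apex, while any fit on the axial 2D projection shows the
opposite ordering — the qualitative 3D-vs-2D contrast the pipeline is
designed to resolve.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .register import AffineTransform, apply_transform
from .volume import Volume

__all__ = [
    "PhantomSpec",
    "InstrumentConfig",
    "GroundTruth",
    "PhantomOutput",
    "generate_phantom",
    "acquisition_time_minutes",
    "helix_centerline",
    "write_ground_truth_txt",
    "read_ground_truth_txt",
]

NF_CHANNEL = "nf"  # neurofilament, 520 nm excitation (Cy3)
HC_CHANNEL = "hc"  # inner hair cells, 635 nm excitation (Cy5)


# --------------------------------------------------------------------------- #
# specs


@dataclass
class InstrumentConfig:
    """Acquisition geometry and timing of the SLOT instrument.

    Defaults follow the real instrument: 0.3° rotational steps, a
    2000 × 1800 px detector at 1.66 μm/px, 7 s per projection image, and an
    index-matching medium of n = 1.552. Desk-scale simulations override the
    angular step and detector size to match the phantom grid.
    """

    angle_step_deg: float = 0.3
    n_pixels_x: int = 2000
    n_pixels_y: int = 1800
    pixel_pitch_um: float = 1.66
    seconds_per_image: float = 7.0
    excitation_channels: list = field(
        default_factory=lambda: [
            {"wavelength_nm": 520, "emission_filter_label": "F37-565"},
            {"wavelength_nm": 635, "emission_filter_label": "F37-679"},
        ]
    )
    refractive_index_medium: float = 1.552

    def __post_init__(self) -> None:
        if self.angle_step_deg <= 0:
            raise ValueError("angle_step_deg must be > 0")
        n = 360.0 / self.angle_step_deg
        if abs(n - round(n)) > 1e-9:
            raise ValueError("360 must be an integer multiple of angle_step_deg")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be > 0")
        if self.n_pixels_x <= 0 or self.n_pixels_y <= 0:
            raise ValueError("detector dimensions must be positive")

    @property
    def n_angles(self) -> int:
        return int(round(360.0 / self.angle_step_deg))

    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * self.angle_step_deg


def acquisition_time_minutes(cfg: InstrumentConfig) -> float:
    """Total rotation-series acquisition time in minutes.

    One projection image per rotational step over a full 360° turn, e.g.
    0.3° steps at 7 s/image give 1200 images and 140 min per channel.
    """
    return cfg.n_angles * cfg.seconds_per_image / 60.0


@dataclass
class PhantomSpec:
    """Parametric description of the synthetic cochlea.

    All lengths in micrometres. ``intensities`` are expected photon counts
    per voxel (Poisson noise is applied on these values);
    ``absorption_coeff`` are Beer–Lambert coefficients per μm.
    """

    turns: float = 1.5
    radius_base_um: float = 280.0
    radius_apex_um: float = 70.0
    pitch_um: float = 1300.0  # axial rise per revolution
    tube_radius_um: float = 20.0
    haircell_offset_um: float = 45.0
    haircell_spacing_um: float = 25.0
    shell_thickness_um: float = 24.0
    shell_clearance_um: float = 40.0
    intensities: dict = field(
        default_factory=lambda: {
            "tube": 120.0,
            "spots": 150.0,
            "shell": 30.0,
            "background": 4.0,
            "hc_background": 10.0,
            "shell_hc": 60.0,
        }
    )
    absorption_coeff: dict = field(
        default_factory=lambda: {"shell": 4.0e-3, "interior": 8.0e-4}
    )
    chromatic_scale: tuple = (1.01, 1.02, 0.985)  # (z, y, x)
    chromatic_shift_um: tuple = (12.0, -18.0, 8.0)  # (z, y, x)
    noise: dict = field(
        default_factory=lambda: {
            "gaussian_sd": 2.0,
            "poisson": True,
            "extinction_gaussian_sd": 5.0e-5,
        }
    )
    n_bright_spots: int = 0  # optional nuisance artifacts, off by default
    seed: int = 1234
    voxel_size_um: float = 8.0
    grid_shape: tuple = (272, 112, 112)  # (nz, ny, nx)

    def validate(self) -> None:
        if not self.turns > 0:
            raise ValueError("turns must be > 0 (degenerate helix)")
        if self.radius_base_um <= 0 or self.radius_apex_um <= 0:
            raise ValueError("helix radii must be positive")
        if self.pitch_um < 0:
            raise ValueError("pitch_um must be >= 0")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be > 0")
        if any(int(n) <= 0 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be three positive integers")
        if self.tube_radius_um < 2.0 * self.voxel_size_um:
            raise ValueError(
                "tube_radius_um must be >= 2 voxels so the tube survives voxelization"
            )
        # the helix plus shell must fit inside the grid
        half = np.asarray(self.grid_shape, float) * self.voxel_size_um / 2.0  # (z,y,x)
        sz, sy, sx = self._shell_semiaxes()
        margin = self.shell_thickness_um + 2.0 * self.voxel_size_um
        if sz + margin > half[0] or sy + margin > half[1] or sx + margin > half[2]:
            raise ValueError(
                "helix plus shell exceeds the grid: enlarge grid_shape or shrink geometry"
            )

    def _shell_semiaxes(self) -> tuple[float, float, float]:
        r_max = max(self.radius_base_um, self.radius_apex_um) + max(
            self.haircell_offset_um, 0.0
        )
        sxy = r_max + self.tube_radius_um + self.shell_clearance_um
        sz = (
            self.pitch_um * self.turns / 2.0
            + self.tube_radius_um
            + self.shell_clearance_um
        )
        return sz, sxy, sxy

    # -- YAML round trip -----------------------------------------------------
    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        for k in ("chromatic_scale", "chromatic_shift_um", "grid_shape"):
            d[k] = list(d[k])
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PhantomSpec":
        p = Path(str(source))
        text = p.read_text() if p.is_file() else str(source)
        d = yaml.safe_load(text)
        for k in ("chromatic_scale", "chromatic_shift_um", "grid_shape"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# --------------------------------------------------------------------------- #
# analytic centerline


def helix_centerline(spec: PhantomSpec, n_samples: int = 4000):
    """Sample the conical-helix centerline and its analytic curvature.

    Returns ``(points_zyx_um, arc_um, radius_um)`` where points are
    grid-centered physical coordinates in (z, y, x) order, ``arc_um`` is the
    cumulative arc length and ``radius_um`` the curvature radius
    ``1/κ = |r'|³ / |r' × r''|`` at each sample.
    """
    theta_max = 2.0 * np.pi * spec.turns
    th = np.linspace(0.0, theta_max, n_samples)
    b = (spec.radius_apex_um - spec.radius_base_um) / theta_max  # dρ/dθ
    rho = spec.radius_base_um + b * th
    c = spec.pitch_um / (2.0 * np.pi)  # dz/dθ
    height = spec.pitch_um * spec.turns

    x = rho * np.cos(th)
    y = rho * np.sin(th)
    z = c * th - height / 2.0
    pts = np.stack([z, y, x], axis=1)

    d1 = np.stack(
        [
            np.full_like(th, c),
            b * np.sin(th) + rho * np.cos(th),
            b * np.cos(th) - rho * np.sin(th),
        ],
        axis=1,
    )
    d2 = np.stack(
        [
            np.zeros_like(th),
            2.0 * b * np.cos(th) - rho * np.sin(th),
            -2.0 * b * np.sin(th) - rho * np.cos(th),
        ],
        axis=1,
    )
    cross = np.cross(d1, d2)
    speed = np.linalg.norm(d1, axis=1)
    kappa = np.linalg.norm(cross, axis=1) / speed**3
    with np.errstate(divide="ignore"):
        radius = np.where(kappa > 0, 1.0 / kappa, np.inf)

    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(chord)])
    return pts, arc, radius


@dataclass
class GroundTruth:
    """Analytic truth of the pre-noise, pre-chromatic-transform phantom."""

    centerline_um: np.ndarray  # (N, 3) grid-centered μm, (z, y, x)
    arc_um: np.ndarray  # (N,) cumulative arc length
    curvature_radius_um: np.ndarray  # (N,)
    length_um: float
    channel_transform: AffineTransform  # correction HC→NF that registration recovers

    def radius_at_nearest(self, points_zyx_um: np.ndarray) -> np.ndarray:
        """Ground-truth curvature radius at the centerline point nearest each query."""
        tree = cKDTree(self.centerline_um)
        _, idx = tree.query(np.atleast_2d(points_zyx_um))
        return self.curvature_radius_um[idx]


@dataclass
class PhantomOutput:
    """Volumes produced by :func:`generate_phantom`.

    ``fluorescence``/``extinction`` are keyed by channel (``"nf"``,
    ``"hc"``); the hair-cell channel is resampled through the true chromatic
    transform before noise, as in a real two-wavelength acquisition.
    ``absorption`` is the clean, untransformed absorption map and
    ``tube_mask`` the ground-truth voxelization of the neurofilament tube.
    """

    fluorescence: dict
    extinction: dict
    absorption: Volume
    tube_mask: Volume
    ground_truth: GroundTruth
    spec: PhantomSpec


# --------------------------------------------------------------------------- #
# rasterization helpers


def _grid_coords_um(spec: PhantomSpec):
    nz, ny, nx = (int(v) for v in spec.grid_shape)
    h = spec.voxel_size_um
    z = (np.arange(nz) - (nz - 1) / 2.0) * h
    y = (np.arange(ny) - (ny - 1) / 2.0) * h
    x = (np.arange(nx) - (nx - 1) / 2.0) * h
    return z, y, x


def _tube_profile(spec: PhantomSpec, centerline: np.ndarray) -> np.ndarray:
    """Antialiased tube occupancy in [0, 1] via distance to the centerline."""
    z, y, x = _grid_coords_um(spec)
    h = spec.voxel_size_um
    # dense resampling so point-to-sample distance ≈ point-to-curve distance
    chord = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(chord)])
    s = np.arange(0.0, arc[-1], h / 3.0)
    dense = np.stack([np.interp(s, arc, centerline[:, i]) for i in range(3)], axis=1)
    tree = cKDTree(dense)

    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    d, _ = tree.query(pts, workers=-1)
    occ = np.clip((spec.tube_radius_um - d) / h + 0.5, 0.0, 1.0)
    return occ.reshape(spec.grid_shape).astype(np.float32)


def _shell_fields(spec: PhantomSpec):
    """Ellipsoidal shell band and interior mask."""
    z, y, x = _grid_coords_um(spec)
    sz, sy, sx = spec._shell_semiaxes()
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    e = np.sqrt((zz / sz) ** 2 + (yy / sy) ** 2 + (xx / sx) ** 2)
    # signed distance to the ellipsoid surface via first-order normalization
    grad = (
        np.sqrt((zz / sz**2) ** 2 + (yy / sy**2) ** 2 + (xx / sx**2) ** 2)
        / np.maximum(e, 1e-9)
    )
    dist = (e - 1.0) / np.maximum(grad, 1e-12)
    shell = ((dist >= 0.0) & (dist <= spec.shell_thickness_um)).astype(np.float32)
    interior = (dist < 0.0).astype(np.float32)
    return shell, interior


def _haircell_spots(spec: PhantomSpec) -> np.ndarray:
    """Point-like hair-cell row: Gaussian spots offset radially from the tube."""
    theta_max = 2.0 * np.pi * spec.turns
    th = np.linspace(0.0, theta_max, 8000)
    b = (spec.radius_apex_um - spec.radius_base_um) / theta_max
    rho = spec.radius_base_um + b * th + spec.haircell_offset_um
    c = spec.pitch_um / (2.0 * np.pi)
    height = spec.pitch_um * spec.turns
    pts = np.stack(
        [c * th - height / 2.0, rho * np.sin(th), rho * np.cos(th)], axis=1
    )
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(chord)])
    s = np.arange(0.0, arc[-1], spec.haircell_spacing_um)
    centers = np.stack([np.interp(s, arc, pts[:, i]) for i in range(3)], axis=1)

    h = spec.voxel_size_um
    nz, ny, nx = (int(v) for v in spec.grid_shape)
    out = np.zeros((nz, ny, nx), dtype=np.float32)
    sigma = max(6.0, 0.75 * h)  # μm; point-like at desk-scale voxels
    r_sup = int(np.ceil(3.0 * sigma / h))
    ctr = (np.asarray([nz, ny, nx], float) - 1.0) / 2.0
    offs = np.arange(-r_sup, r_sup + 1)
    oz, oy, ox = np.meshgrid(offs, offs, offs, indexing="ij")
    for cpt in centers:
        cvox = cpt / h + ctr
        base = np.round(cvox).astype(int)
        iz, iy, ix = base[0] + oz, base[1] + oy, base[2] + ox
        ok = (
            (iz >= 0) & (iz < nz) & (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
        )
        dz = (iz - cvox[0]) * h
        dy = (iy - cvox[1]) * h
        dx = (ix - cvox[2]) * h
        g = np.exp(-(dz**2 + dy**2 + dx**2) / (2.0 * sigma**2))
        np.add.at(out, (iz[ok], iy[ok], ix[ok]), g[ok].astype(np.float32))
    return out


def _add_bright_spots(rng, spec: PhantomSpec, *volumes: np.ndarray) -> None:
    """Optional nuisance artifacts: dye agglomerations / scattering bubbles."""
    nz, ny, nx = (int(v) for v in spec.grid_shape)
    amp = 4.0 * spec.intensities["tube"]
    for _ in range(spec.n_bright_spots):
        cz, cy, cx = (rng.uniform(0.25, 0.75) * np.array([nz, ny, nx])).astype(int)
        r = int(max(1, round(12.0 / spec.voxel_size_um)))
        for vol in volumes:
            vol[cz - r : cz + r + 1, cy - r : cy + r + 1, cx - r : cx + r + 1] += amp


# --------------------------------------------------------------------------- #
# generator


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Build per-channel emission and extinction volumes plus ground truth.

    The neurofilament channel contains the tube, the autofluorescent shell
    and a low uniform background; the hair-cell channel contains the spot
    row, a stronger nonspecific background and a bright shell surface. The
    hair-cell channel (fluorescence and extinction alike) is resampled
    through the true chromatic scale/shift before noise is applied. All
    randomness derives from ``spec.seed``: the same seed reproduces the
    volumes bit for bit.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h = spec.voxel_size_um
    inten = spec.intensities

    centerline, arc, radius = helix_centerline(spec)
    gen_transform = AffineTransform(
        tuple(spec.chromatic_scale), tuple(spec.chromatic_shift_um)
    )
    gt = GroundTruth(
        centerline_um=centerline,
        arc_um=arc,
        curvature_radius_um=radius,
        length_um=float(arc[-1]),
        channel_transform=gen_transform.inverse(),
    )

    tube = _tube_profile(spec, centerline)
    shell, interior = _shell_fields(spec)
    spots = _haircell_spots(spec)

    nf = (
        inten["background"]
        + inten["tube"] * tube
        + inten["shell"] * shell
    ).astype(np.float32)
    hc = (
        inten["hc_background"] * np.maximum(interior, shell)
        + inten["spots"] * spots
        + inten["shell_hc"] * shell
    ).astype(np.float32)
    absorption = (
        spec.absorption_coeff["interior"] * interior
        + spec.absorption_coeff["shell"] * shell
    ).astype(np.float32)

    if spec.n_bright_spots > 0:
        _add_bright_spots(rng, spec, nf, hc)

    meta = {"phantom_seed": spec.seed}
    vol_nf = Volume(nf, h, {**meta, "channel": NF_CHANNEL, "kind": "fluorescence"})
    vol_hc = Volume(hc, h, {**meta, "channel": HC_CHANNEL, "kind": "fluorescence"})
    vol_abs = Volume(absorption, h, {**meta, "kind": "absorption"})

    # chromatic aberration of the 635 nm acquisition
    vol_hc = apply_transform(vol_hc, gen_transform)
    ext_nf = vol_abs.copy()
    ext_hc = apply_transform(vol_abs, gen_transform)
    ext_nf.meta.update(channel=NF_CHANNEL)
    ext_hc.meta.update(channel=HC_CHANNEL)

    # shot + detector noise, all drawn from the one seeded generator
    noise = spec.noise
    for vol in (vol_nf, vol_hc):
        if noise.get("poisson", False):
            vol.data = rng.poisson(np.clip(vol.data, 0, None)).astype(np.float32)
        sd = float(noise.get("gaussian_sd", 0.0))
        if sd > 0:
            vol.data = vol.data + rng.normal(0.0, sd, vol.data.shape).astype(np.float32)
    sd_ext = float(noise.get("extinction_gaussian_sd", 0.0))
    for vol in (ext_nf, ext_hc):
        if sd_ext > 0:
            noisy = vol.data + rng.normal(0.0, sd_ext, vol.data.shape).astype(np.float32)
            vol.data = np.clip(noisy, 0.0, None)  # absorption cannot be negative

    tube_mask = Volume((tube >= 0.5).astype(np.uint8), h, {"kind": "tube_mask"})
    return PhantomOutput(
        fluorescence={NF_CHANNEL: vol_nf, HC_CHANNEL: vol_hc},
        extinction={NF_CHANNEL: ext_nf, HC_CHANNEL: ext_hc},
        absorption=vol_abs,
        tube_mask=tube_mask,
        ground_truth=gt,
        spec=spec,
    )


# --------------------------------------------------------------------------- #
# ground-truth TXT (x y z radius per line)


def write_ground_truth_txt(gt: GroundTruth, path, every: int = 1) -> Path:
    """Whitespace-delimited ``x y z radius_um`` table of the centerline."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pts = gt.centerline_um[::every]
    rad = gt.curvature_radius_um[::every]
    table = np.column_stack([pts[:, 2], pts[:, 1], pts[:, 0], rad])
    np.savetxt(path, table, fmt="%.4f", header="x_um y_um z_um radius_um")
    return path


def read_ground_truth_txt(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an ``x y z radius`` table back as ``(points_zyx_um, radius_um)``."""
    table = np.loadtxt(path)
    pts = table[:, [2, 1, 0]]
    return pts, table[:, 3]
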