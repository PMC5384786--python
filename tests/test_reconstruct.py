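"""Filtered back projection: analytic oracles, linearity, sampling behavior."""

import numpy as np
import pytest
from skimage.transform import iradon

from slotpipe import InstrumentConfig, Volume, fbp_reconstruct, project_fluorescence, round_trip_error
from slotpipe.projector import ProjectionStack


def disk_sinogram(n=101, R=20.0, n_angles=360):
    """Analytic parallel-beam sinogram of a centered unit disk: 2√(R²−s²)."""
    ctr = (n - 1) / 2
    s = np.arange(n) - ctr
    prof = 2.0 * np.sqrt(np.clip(R**2 - s**2, 0, None)).astype(np.float32)
    angles = np.arange(n_angles) * 360.0 / n_angles
    images = np.tile(prof, (n_angles, 1, 1))
    return ProjectionStack(images=images, angles_deg=angles, pixel_pitch_um=1.0)


def gaussian_sinogram(blobs, n=128, n_angles=360):
    """Exact line integrals of a sum of isotropic 2D Gaussians."""
    ctr = (n - 1) / 2
    t = np.arange(n) - ctr
    angles = np.arange(n_angles) * 360.0 / n_angles
    th = np.deg2rad(angles)
    images = np.zeros((n_angles, 1, n), np.float32)
    for oy, ox, sig, amp in blobs:
        t0 = oy * np.cos(th) + ox * np.sin(th)
        images[:, 0, :] += (
            amp * np.sqrt(2 * np.pi) * sig
            * np.exp(-((t[None, :] - t0[:, None]) ** 2) / (2 * sig**2))
        ).astype(np.float32)
    return ProjectionStack(images=images, angles_deg=angles, pixel_pitch_um=1.0)


BLOBS = [(0, 0, 18, 1.0), (25, -10, 3, 0.8), (-30, 15, 2.5, 0.6), (10, 35, 4, 0.7)]


def blob_reference(n=128):
    ctr = (n - 1) / 2
    yy, xx = np.meshgrid(np.arange(n) - ctr, np.arange(n) - ctr, indexing="ij")
    ref = np.zeros((n, n), np.float32)
    for oy, ox, sig, amp in BLOBS:
        ref += amp * np.exp(-((yy - oy) ** 2 + (xx - ox) ** 2) / (2 * sig**2))
    cyl = (yy**2 + xx**2) <= (n / 2) ** 2
    return np.where(cyl, ref, 0.0), cyl


class TestFBPOracles:
    def test_zero_stack_reconstructs_to_zero(self):
        stack = ProjectionStack(
            images=np.zeros((16, 2, 32), np.float32),
            angles_deg=np.arange(16) * 22.5,
            pixel_pitch_um=1.0,
        )
        vol = fbp_reconstruct(stack, "ramp")
        assert np.all(vol.data == 0)

    def test_analytic_disk_mean_value(self):
        stack = disk_sinogram()
        rec = fbp_reconstruct(stack, "ramp")
        n = rec.shape[1]
        ctr = (n - 1) / 2
        yy, xx = np.meshgrid(np.arange(n) - ctr, np.arange(n) - ctr, indexing="ij")
        inner = (yy**2 + xx**2) <= (0.8 * 20.0) ** 2
        assert rec.data[0][inner].mean() == pytest.approx(1.0, abs=0.05)

    def test_point_source_round_trip_argmax(self):
        data = np.zeros((3, 64, 64), np.float32)
        data[1, 40, 25] = 1.0
        cfg = InstrumentConfig(angle_step_deg=2.0)
        rec = fbp_reconstruct(project_fluorescence(Volume(data, 1.0), cfg), "ramp")
        assert np.unravel_index(rec.data.argmax(), rec.shape) == (1, 40, 25)

    def test_matches_independent_iradon_on_symmetric_phantom(self):
        # rotationally symmetric phantom → immune to axis conventions
        stack = disk_sinogram(n=101, R=20.0, n_angles=180)
        ours = fbp_reconstruct(stack, "ramp").data[0]
        theirs = iradon(
            stack.images[:, 0, :].T,
            theta=stack.angles_deg,
            filter_name="ramp",
            circle=True,
            output_size=101,
        )
        n = 101
        ctr = (n - 1) / 2
        yy, xx = np.meshgrid(np.arange(n) - ctr, np.arange(n) - ctr, indexing="ij")
        inner = (yy**2 + xx**2) <= 18.0**2
        assert np.allclose(ours[inner], theirs[inner], atol=0.05)


class TestFBPProperties:
    def test_linearity(self, rng):
        s1 = gaussian_sinogram(BLOBS[:2], n_angles=90)
        s2 = gaussian_sinogram(BLOBS[2:], n_angles=90)
        a, b = 2.5, -0.7
        combo = ProjectionStack(
            images=a * s1.images + b * s2.images,
            angles_deg=s1.angles_deg,
            pixel_pitch_um=1.0,
        )
        lhs = fbp_reconstruct(combo, "hann").data
        rhs = a * fbp_reconstruct(s1, "hann").data + b * fbp_reconstruct(s2, "hann").data
        assert np.allclose(lhs, rhs, atol=1e-4)

    def test_nrmse_monotone_in_angle_count(self):
        ref, cyl = blob_reference()
        errs = []
        for n_angles in (16, 32, 64, 128, 256, 512, 1024):
            rec = fbp_reconstruct(gaussian_sinogram(BLOBS, n_angles=n_angles), "ramp").data[0]
            errs.append(np.linalg.norm((rec - ref)[cyl]) / np.linalg.norm(ref[cyl]))
        assert np.all(np.diff(errs) < 0)

    def test_half_and_full_coverage_agree(self):
        full = gaussian_sinogram(BLOBS, n_angles=360)
        half = ProjectionStack(
            images=full.images[:180],
            angles_deg=full.angles_deg[:180],
            pixel_pitch_um=1.0,
        )
        r_full = fbp_reconstruct(full, "ramp").data
        r_half = fbp_reconstruct(half, "ramp").data
        nrmse = np.linalg.norm(r_full - r_half) / np.linalg.norm(r_full)
        assert nrmse < 0.02


class TestRoundTripError:
    def smooth_blob(self, n=96, sig=12.0):
        ctr = (n - 1) / 2
        yy, xx = np.meshgrid(np.arange(n) - ctr, np.arange(n) - ctr, indexing="ij")
        b = np.exp(-((yy - 5) ** 2 + (xx + 8) ** 2) / (2 * sig**2)).astype(np.float32)
        return Volume(b[None], 1.0)

    def test_smooth_phantom_many_angles_small_error(self):
        err = round_trip_error(self.smooth_blob(), InstrumentConfig(angle_step_deg=0.3), "hann")
        assert err < 0.05

    def test_fewer_angles_strictly_worse(self):
        vol = self.smooth_blob()
        err_many = round_trip_error(vol, InstrumentConfig(angle_step_deg=0.3), "hann")
        err_few = round_trip_error(vol, InstrumentConfig(angle_step_deg=30.0), "hann")
        assert err_few > err_many

    def test_zero_volume_gives_zero(self):
        vol = Volume(np.zeros((2, 32, 32), np.float32), 1.0)
        assert round_trip_error(vol, InstrumentConfig(angle_step_deg=10.0)) == 0.0


class TestInputValidation:
    def test_nonuniform_angles_rejected(self):
        stack = ProjectionStack(
            images=np.zeros((9, 1, 16), np.float32),
            angles_deg=np.concatenate([np.arange(8) * 10.0, [95.0]]),
            pixel_pitch_um=1.0,
        )
        with pytest.raises(ValueError, match="uniform"):
            fbp_reconstruct(stack)

    def test_too_few_angles_rejected(self):
        stack = ProjectionStack(
            images=np.zeros((4, 1, 16), np.float32),
            angles_deg=np.arange(4) * 90.0,
            pixel_pitch_um=1.0,
        )
        with pytest.raises(ValueError, match="under-sampled"):
            fbp_reconstruct(stack)

    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError, match="filter"):
            fbp_reconstruct(disk_sinogram(n_angles=16), "shepp")
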