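"""Skeleton length, three-point circle fits, curvature profiles, MIP."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slotpipe import (
    LabelMask,
    Volume,
    base_apex_ratio,
    centerline_length_um,
    circle_through_3_points,
    colorize_curvature,
    mip,
    profile_from_points,
    skeletonize,
)
from slotpipe.morphometry import CurvatureProfile

from conftest import small_spec


def brute_force_circumcircle(p1, p2, p3):
    """Independent oracle: solve the equidistance equations by least squares,
    constrained to the triangle's plane."""
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    normal = np.cross(p2 - p1, p3 - p1)
    A = np.array([2 * (p2 - p1), 2 * (p3 - p1), normal])
    b = np.array([p2 @ p2 - p1 @ p1, p3 @ p3 - p1 @ p1, normal @ p1])
    center = np.linalg.lstsq(A, b, rcond=None)[0]
    return np.linalg.norm(p1 - center), center


def synthetic_profile(radii, arc=None):
    radii = np.asarray(radii, float)
    arc = np.linspace(0, 1000, len(radii)) if arc is None else arc
    return CurvatureProfile(arc, np.zeros((len(radii), 3)), radii, "3D", 25.0, 4)


class TestCircleFit:
    def test_unit_semicircle(self):
        r, c = circle_through_3_points((1, 0, 0), (0, 1, 0), (-1, 0, 0))
        assert r == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(c, 0.0, atol=1e-12)

    def test_collinear_reports_infinite(self):
        r, c = circle_through_3_points((0, 0, 0), (1, 0, 0), (2, 0, 0))
        assert np.isinf(r)
        assert c is None

    def test_against_brute_force_oracle(self, rng):
        for _ in range(1000):
            pts = rng.normal(0, 100, (3, 3))
            r, c = circle_through_3_points(*pts)
            r_ref, c_ref = brute_force_circumcircle(*pts)
            if np.isinf(r):
                continue
            assert abs(r - r_ref) <= 1e-6 * r_ref
            assert np.allclose(c, c_ref, rtol=1e-6, atol=1e-6 * r_ref)
            # all three points lie on the returned circle
            d = np.linalg.norm(pts - c, axis=1)
            assert np.allclose(d, r, rtol=1e-9)

    @given(st.permutations([0, 1, 2]))
    @settings(deadline=None, max_examples=6)
    def test_permutation_invariant(self, perm):
        pts = np.array([[10.0, -3.0, 2.0], [4.0, 8.0, -1.0], [-6.0, 1.0, 5.0]])
        r_ref, c_ref = circle_through_3_points(*pts)
        r, c = circle_through_3_points(*pts[list(perm)])
        assert r == pytest.approx(r_ref, rel=1e-12)
        assert np.allclose(c, c_ref, atol=1e-9)


class TestSkeleton:
    def test_straight_tube_length(self):
        n = 110
        mask = np.zeros((n, 16, 16), bool)
        zz, yy, xx = np.meshgrid(
            np.arange(n), np.arange(16), np.arange(16), indexing="ij"
        )
        mask[(np.abs(yy - 8) ** 2 + np.abs(xx - 8) ** 2 <= 9) & (zz >= 5) & (zz < 105)] = True
        skel = skeletonize(LabelMask(mask, 2.0), prune_below_um=10.0)
        assert skel.longest_path_um == pytest.approx(100 * 2.0, abs=3 * 2.0)

    def test_solid_ball_degenerates_to_point_like_skeleton(self):
        n = 31
        zz, yy, xx = np.meshgrid(*[np.arange(n) - 15] * 3, indexing="ij")
        mask = (zz**2 + yy**2 + xx**2) <= 12**2
        skel = skeletonize(LabelMask(mask, 1.0), prune_below_um=15.0)
        assert skel.total_length_um < 24.0  # well under the ball diameter

    def test_voxelized_helix_longest_path_length(self, small_phantom):
        mask = LabelMask(small_phantom.tube_mask.data.astype(bool),
                         small_phantom.tube_mask.voxel_size_um)
        skel = skeletonize(mask, prune_below_um=40.0)
        gt_len = small_phantom.ground_truth.length_um
        assert centerline_length_um(skel) == pytest.approx(gt_len, rel=0.05)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            skeletonize(LabelMask(np.zeros((8, 8, 8), bool), 1.0))

    def test_total_length_stable_under_dilation(self, small_phantom):
        from scipy import ndimage

        base = small_phantom.tube_mask.data.astype(bool)
        h = small_phantom.tube_mask.voxel_size_um
        dilated = ndimage.binary_dilation(base, np.ones((3, 3, 3), bool))
        l0 = centerline_length_um(skeletonize(LabelMask(base, h), 40.0))
        l1 = centerline_length_um(skeletonize(LabelMask(dilated, h), 40.0))
        assert abs(l1 - l0) / l0 < 0.05


class TestCurvatureProfile:
    def test_planar_circle_radius_exact(self):
        R = 200.0
        th = np.linspace(0, 1.8 * np.pi, 400)
        pts = np.stack([np.zeros_like(th), R * np.sin(th), R * np.cos(th)], axis=1)
        prof = profile_from_points(pts, spacing_um=20.0, half_window=3)
        assert np.allclose(prof.radius_um, R, rtol=0.01)

    def test_constant_helix_3d_and_2d_closed_forms(self):
        from slotpipe import helix_centerline

        a, c = 150.0, 50.0
        spec = small_spec(
            turns=2.0, radius_base_um=a, radius_apex_um=a,
            pitch_um=2 * np.pi * c, grid_shape=(160, 96, 96),
        )
        pts, _, _ = helix_centerline(spec, 8000)
        p3 = profile_from_points(pts, spacing_um=10.0, half_window=2, space="3D")
        p2 = profile_from_points(pts, spacing_um=10.0, half_window=2, space="2D-MIP")
        assert np.allclose(p3.radius_um, (a**2 + c**2) / a, rtol=0.01)
        assert np.allclose(p2.radius_um, a, rtol=0.01)

    def test_rigid_motion_invariance(self, rng):
        th = np.linspace(0, 4 * np.pi, 600)
        pts = np.stack([30 * th, 150 * np.sin(th), 150 * np.cos(th)], axis=1)
        ref = profile_from_points(pts, 25.0, 4).radius_um
        for _ in range(3):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            R = np.array(
                [
                    [1 - 2 * (y**2 + z**2), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                    [2 * (x * y + w * z), 1 - 2 * (x**2 + z**2), 2 * (y * z - w * x)],
                    [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x**2 + y**2)],
                ]
            )
            moved = pts @ R.T + rng.normal(0, 50, 3)
            got = profile_from_points(moved, 25.0, 4).radius_um
            assert np.allclose(got, ref, rtol=1e-6)

    def test_too_short_path_names_minimum(self):
        pts = np.stack([np.linspace(0, 40, 10)] * 3, axis=1)
        with pytest.raises(ValueError, match="minimum"):
            profile_from_points(pts, spacing_um=25.0, half_window=4)


class TestBaseApexRatio:
    def test_printed_3d_radii_give_058(self):
        ba = base_apex_ratio(synthetic_profile([150.0] * 50 + [260.0] * 50))
        assert ba.ratio_reported == 0.58

    def test_printed_2d_radii_round_to_26(self):
        ba = base_apex_ratio(synthetic_profile([1819.0] * 50 + [693.0] * 50))
        assert ba.ratio_reported == 2.62
        assert round(ba.ratio, 1) == 2.6

    def test_constant_profile_ratio_one(self):
        ba = base_apex_ratio(synthetic_profile([100.0] * 40))
        assert ba.ratio == pytest.approx(1.0)

    def test_infinite_window_median_fails(self):
        radii = [np.inf] * 20 + [100.0] * 80
        with pytest.raises(ValueError, match="infinite"):
            base_apex_ratio(synthetic_profile(radii), fraction=0.1)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            base_apex_ratio(synthetic_profile([1.0] * 10), fraction=0.9)


class TestMip:
    def test_single_bright_voxel(self):
        data = np.zeros((5, 6, 7), np.float32)
        data[2, 3, 4] = 9.0
        img = mip(Volume(data, 1.0), axis=0)
        assert img[3, 4] == 9.0
        assert img.sum() == 9.0

    def test_masked_mip_bounded_by_full_mip(self, rng):
        data = rng.random((6, 10, 10)).astype(np.float32)
        vol = Volume(data, 1.0)
        mask = LabelMask(rng.random((6, 10, 10)) > 0.5, 1.0)
        assert np.all(mip(vol) >= mip(vol, mask=mask))

    def test_constant_volume(self):
        vol = Volume(np.full((3, 4, 5), 2.5, np.float32), 1.0)
        assert np.all(mip(vol, axis=1) == 2.5)


class TestColorize:
    def test_extremes_and_midpoint(self):
        prof = synthetic_profile([50.0, 300.0, 175.0, np.inf])
        _, rgb = colorize_curvature(prof, (50.0, 300.0))
        assert np.allclose(rgb[0], [1, 0, 0])  # smallest radius → pure red
        assert np.allclose(rgb[1], [0, 0, 1])  # largest → pure blue
        assert np.allclose(rgb[2], [0.5, 0, 0.5])  # midpoint → linear blend
        assert np.allclose(rgb[3], [0, 0, 1])  # infinite → blue extreme

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            colorize_curvature(synthetic_profile([1.0]), (10.0, 10.0))
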