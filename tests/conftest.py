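"""Shared fixtures: phantoms and pipeline stages reused across test modules.

The expensive desk-scale end-to-end run and the small noisy phantom are
session-scoped so each is computed once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

from slotpipe import (
    InstrumentConfig,
    PhantomSpec,
    curvature_profile,
    desk_instrument,
    fbp_reconstruct,
    generate_phantom,
    project_fluorescence,
    segment_seeded,
    skeletonize,
)


def small_spec(**overrides) -> PhantomSpec:
    """Gentle-pitch phantom small enough for unit tests (no curvature reversal)."""
    kw = dict(
        turns=1.25,
        radius_base_um=140.0,
        radius_apex_um=60.0,
        pitch_um=400.0,
        tube_radius_um=16.0,
        haircell_offset_um=35.0,
        grid_shape=(88, 72, 72),
        seed=11,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def small_phantom():
    """Small noisy phantom with its chromatic channel pair."""
    return generate_phantom(small_spec())


@pytest.fixture(scope="session")
def desk_run():
    """Default desk-scale phantom taken through projection, FBP,
    segmentation and skeleton/curvature analysis (pipeline defaults)."""
    spec = PhantomSpec()
    out = generate_phantom(spec)
    gt = out.ground_truth
    cfg = desk_instrument(spec, angle_step_deg=1.5)
    stack = project_fluorescence(out.fluorescence["nf"], cfg)
    recon = fbp_reconstruct(stack, "hann")
    seeds = [
        tuple(int(round(v)) for v in recon.um_to_voxel(gt.centerline_um[i])[0])
        for i in (200, 2000, 3800)
    ]
    mask = segment_seeded(recon, seeds, threshold=60.0, min_component_voxels=50)
    skel = skeletonize(mask, prune_below_um=40.0)
    prof_kwargs = dict(
        spacing_um=25.0, half_window=6, smooth_window_um=100.0,
        start_near=gt.centerline_um[0],
    )
    p3 = curvature_profile(skel, space="3D", **prof_kwargs)
    p2 = curvature_profile(skel, space="2D-MIP", drop_axis=0, **prof_kwargs)
    return {
        "spec": spec,
        "phantom": out,
        "gt": gt,
        "instrument": cfg,
        "recon": recon,
        "mask": mask,
        "skel": skel,
        "p3": p3,
        "p2": p2,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
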