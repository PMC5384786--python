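"""Recover the chromatic aberration between the two excitation channels.

The two fluorophores label different structures, so registration uses the
extinction (transmission) volumes, which image the same absorbing anatomy
in both channels. The estimated scale+shift is then applied to the
hair-cell fluorescence volume.
"""

import numpy as np

from slotpipe import PhantomSpec, apply_transform, estimate_transform, generate_phantom

spec = PhantomSpec(
    turns=1.25, radius_base_um=140, radius_apex_um=60, pitch_um=400,
    tube_radius_um=16, haircell_offset_um=35, grid_shape=(88, 72, 72),
)
out = generate_phantom(spec)
true = out.ground_truth.channel_transform

est = estimate_transform(out.extinction["nf"], out.extinction["hc"])
registered = apply_transform(out.fluorescence["hc"], est)

print(f"true correction:      scale {np.round(true.scale, 4)}, "
      f"shift {np.round(true.translation_um, 2)} μm")
print(f"estimated correction: scale {np.round(est.scale, 4)}, "
      f"shift {np.round(est.translation_um, 2)} μm")
scale_err = np.max(np.abs(np.subtract(est.scale, true.scale)))
shift_err = np.max(np.abs(np.subtract(est.translation_um, true.translation_um)))
print(f"errors: scale {scale_err:.4f}, shift {shift_err / spec.voxel_size_um:.2f} voxels")
# Sub-0.005 scale and sub-half-voxel shift errors mean the hair-cell row
# lands in its true position next to the neurofilament tube.
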