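# Methods

## Scope and design

`slotpipe` implements the complete SLOT measurement chain — rotational
parallel-beam acquisition, filtered back projection (FBP), inter-channel
registration, segmentation, and skeleton/curvature morphometry — against a
synthetic cochlea phantom with closed-form geometry. The phantom is not a
fixture but the package's verification instrument: because its centerline,
arc length, curvature radii and chromatic transform are exact, every
downstream stage has an analytic oracle.

## Phantom

**Geometry.** The labeled neurofilament is a tube of radius `tube_radius_um`
(default 20 μm) around a conical helix: in-plane radius interpolates
linearly in turn angle between `radius_base_um` (280 μm) and
`radius_apex_um` (70 μm) over `turns` (1.5) revolutions, and z rises
linearly at `pitch_um` (1300 μm) per revolution. The defaults deliberately
exaggerate the axial pitch relative to a real murine cochlea. The reason is
the package's central qualitative target: for a helix the 3D curvature
radius is `a + c²/a` (in-plane radius `a`, rise per radian `c`) while the
axial 2D projection sees only `a`; whenever `c² > a_base·a_apex` the
base/apex ordering of the 3D radii is the *opposite* of the projected 2D
ordering. With `c ≈ 207 μm` the default phantom satisfies this (ground
truth: 3D ratio ≈ 0.82, 2D ratio ≈ 2.98), so the pipeline must reproduce
the 3D-vs-2D reversal that motivates measuring curvature in three
dimensions at all. A gentle-pitch configuration (used widely in the tests)
keeps the 3D radius monotone base→apex instead. The number of turns and
pitch are illustrative, not anatomical claims.

**Channels.** The neurofilament channel holds tube + autofluorescent shell
+ low uniform background; the hair-cell channel holds a row of point-like
Gaussian spots (σ = 6 μm, spacing 25 μm along an offset curve 45 μm outside
the tube), a stronger nonspecific background, and a bright shell surface.
The absorption map (ellipsoidal shell at 4·10⁻³ μm⁻¹, interior soft tissue
at 8·10⁻⁴ μm⁻¹) provides the extinction contrast. The hair-cell channel —
fluorescence and extinction alike — is resampled through the true
chromatic transform (per-axis scale ≈ ±2%, shift ≈ 1–2 voxels) before
noise; `GroundTruth.channel_transform` stores the *correcting* transform
that registration must recover.

**Noise.** Poisson shot noise on the fluorescence expectation values
(intensities are expected photon counts, tube 120, spots 150, shell 30,
background 4) followed by additive Gaussian detector noise (sd 2). The
extinction maps receive a small additive Gaussian term (sd 5·10⁻⁵ μm⁻¹,
clipped at zero since absorption is non-negative). All draws come from one
generator seeded by `PhantomSpec.seed`; identical seeds give bit-identical
volumes. Optional bright-spot artifacts (dye agglomerations / bubbles) are
off by default.

**Grid.** Desk-scale default is (272, 112, 112) voxels at 8 μm — tall and
narrow to fit the steep helix with ~3.4 M voxels; the full instrument
geometry (2000×1800 px at 1.66 μm, 0.3° steps) remains reachable through
`InstrumentConfig`. The generator rejects any geometry whose helix + shell
would leave the grid, tubes thinner than two voxels, and non-positive
dimensions.

## Forward model

Fluorescence projection at angle θ is the line integral of emission along
the illumination axis after rotating the volume by −θ (slice-wise 2D
rotation about z, linear interpolation, zeros outside the grid); output
units are intensity·μm. Extinction projections are Beer–Lambert optical
densities, returned log-converted so FBP applies directly. Angles are
counter-clockwise looking down +z, angle 0 illuminating along +x; the
convention is written into each stack's JSON sidecar. Self-absorption of
fluorescence and any optical point-spread function are ignored — the
cleared, index-matched specimen justifies a transparent-emission,
geometric-ray model.

## Reconstruction

Parallel geometry separates into independent 2D problems per detector row.
Each row's sinogram is divided by the pixel pitch (pixel units), filtered
in the frequency domain with the ramp |f| — optionally apodized by a Hann
(default) or Hamming window — after zero-padding to the next power of two
(≥ 2× detector width) to suppress periodic wrap-around, then back-projected
with linear interpolation at detector coordinate `t = y·cosθ + x·sinθ` and
scaled by π/n_angles (correct for uniform coverage of either 180° or
360°). Voxels outside the inscribed cylinder are zeroed (not fully
sampled). The implementation is deterministic, so outputs are reproducible
bit for bit for a given version. Under-sampled (< 8 angles) or non-uniform
stacks are rejected. The Hann default trades a ~3% smooth-phantom
round-trip floor for strong suppression of noise streaks; the pure ramp is
kept for analytic oracle work. With the forward projector in the loop the
round-trip error saturates at the rotation-interpolation floor once the
angular Nyquist criterion is met; sampling studies therefore use analytic
sinograms (disks: `2√(R²−s²)`; Gaussians: exact line integrals).

## Registration

Chromatic aberration in a telecentric scan produces per-axis magnification
and offset, no rotation or shear, so the transform family is scale +
translation about the grid center (scales constrained to (0.5, 2)). Both
extinction volumes are z-scored and the mean squared difference is
minimized with a three-level pyramid (×4, ×2, ×1 local-mean downsampling):
a translation-only grid search (±5 voxels) seeds the coarsest level, then
coordinate descent over the six parameters with four step-halving rounds
per level (translation steps from one voxel down to ~0.1 voxel, scale
steps from 2% down to ~10⁻⁴). The estimator is deterministic and, on the
noisy phantom pair, recovers scale to ~3·10⁻³ and shift to ~0.05 voxels;
accuracy degrades monotonically as extinction noise grows. Featureless
(constant) inputs are rejected. Volumes with structure at the grid border
bias the scale estimate (content scaled past the edge reads as zero); the
phantom's compactly supported anatomy avoids this.

## Segmentation

ITK-SNAP-style interactive segmentation is replaced by a fully specified
seeded region growing: voxels ≥ threshold, 26-connected to a seed, one
3×3×3 closing pass, components below `min_component_voxels` dropped. Seeds
below threshold are reported unusable (warning); if none survive the stage
fails. In the end-to-end pipeline the seeds are taken from the ground-truth
centerline — the stand-in for the operator's clicks — and the default
threshold 60 sits roughly midway between background (≈4) and tube (≈120)
intensity after reconstruction. Erosion for interior masking
(`inner_mask`) uses the 6-connected structuring element; note that n
iterations of 6-connected erosion erode by an L1 (diamond) ball, which
removes less material along diagonals than a Euclidean ball of radius n —
the eroded volume of a ball is accordingly larger than the naive spherical
estimate.

## Morphometry

**Skeleton.** Topology-preserving 3D thinning (Lee's method via
scikit-image) reduces the mask to a one-voxel centerline; voxels become
graph nodes, 26-neighbor links become edges weighted 1/√2/√3 × voxel size.
Endpoint branches shorter than `prune_below_um` (default 40 μm) that end
at a junction are pruned iteratively. The longest weighted
endpoint-to-endpoint path of the heaviest component is the measured
centerline.

**Length.** The raw 26-connected chain overestimates a smooth curve's
length by up to ~10% (stair-step metrication; +9.6% measured on the
default phantom). `SkeletonGraph` reports the raw chain sums (total and
longest path), and `centerline_length_um` reports the headline length on
the longest path smoothed by a 40 μm moving average, which removes the
voxel jitter and is accurate to ~0.3–1.4% on the phantom.

**Curvature.** The longest path is smoothed (100 μm moving average — set
to 0 for analytic centerlines), resampled at uniform `spacing_um`
(default 25 μm), and the curvature radius at sample i is the circumradius
of (s[i−k], s[i], s[i+k]) — radius = |a||b||c|/(4·Area), circumcenter in
the triangle's plane, collinear triples flagged infinite. The fit is
permutation-invariant and rigid-motion-invariant by construction. For 2D
analysis the resampled points are orthogonally projected (one coordinate
dropped; default the z/axial direction, i.e. the plane of the acquisition
MIP) before fitting. The pipeline default half-window is k = 6 (chord
300 μm, well under one turn); the module and CLI default is k = 4. Larger
windows average voxel noise at the cost of resolution: at 8 μm voxels the
sagitta of a 200 μm chord on a 500 μm-radius arc is barely over one voxel,
so k = 4 without smoothing is noise-limited — whence the smoothing default
and the pipeline's k = 6. Every output records the spacing, window and
smoothing used.

**Base/apex statistic.** Profiles are oriented base→apex (the pipeline
anchors the start to the ground-truth base); `base_apex_ratio` takes the
median radius over the first and last `fraction` (default 0.1) of arc
length — medians are robust to endpoint artifacts, where the skeleton ends
inside the tube caps and the three-point window spans the path end. The
ratio is additionally rounded to two decimals for reporting. Windows whose
median is infinite (straight segments) make the ratio undefined and raise.

**Rendering.** `mip` gives (optionally mask-restricted) maximum intensity
projections; `colorize_curvature` maps radii linearly to a red(small) ↔
blue(large) colormap, clipping at the range ends and rendering infinite
radii as the blue extreme.

## Pipeline and reproducibility

`RunConfig` (YAML-serializable, programmatically validated) holds every
stage parameter plus one master seed, fanned out to per-stage seeds through
`numpy.random.SeedSequence` (recorded in the manifest). `run_all` writes
every intermediate artifact — multi-page TIFF volumes and stacks with JSON
sidecars, TXT point/radius tables mirroring the `x y z radius` layout of
the published segmentation-coordinates file, the transform JSON, and a
manifest with SHA-256 checksums, stage parameters and summary metrics. A
failed stage raises an error naming the stage and leaves earlier outputs on
disk. Two runs from the same config and seed are bit-identical.

## What the phantom does and does not show

Passing tests demonstrate that the measurement chain — given
parallel-beam projections of a high-contrast tubular structure — recovers
length to a few percent, curvature radii to ~10% pointwise, chromatic
registration to sub-voxel accuracy, and the qualitative 3D-vs-2D curvature
reversal. The phantom does not model optical point-spread, refraction at
the cuvette, depth-dependent attenuation, spatially varying labeling
density, dendrites branching off the main canal, or anatomically accurate
cochlear dimensions; absolute real-tissue values (e.g. a specific
millimetre length for a given animal) are outside what a synthetic study
can certify. Sample sizes were chosen for desk-scale work: ~3.4 M-voxel
volumes, 240 projection angles, ~90-sample curvature profiles.

## Known limitations

- The rotation-based projector and FBP share the slice-wise interpolation
  model; an axis-offset or axis-tilt between detector and rotation axis is
  not estimated (stacks assert alignment).
- Registration is restricted to scale + translation; deformable or
  rotational misalignment is out of scope.
- Region growing assumes high contrast; it has no regularization against
  leakage through faint bridges beyond the closing/pruning steps.
- The 26-connected chain lengths retained on `SkeletonGraph` carry the
  documented metrication bias; use `centerline_length_um` for calibrated
  lengths.
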