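# Methods

## Problem and scope

Proved bread dough is a foam: gas cells separated by thin lamellae — gas
cell walls (GCWs) — built from a gluten network with embedded wheat-starch
granules. Label-free multiphoton microscopy images the two solid phases
separately: second-harmonic generation (SHG) from the radially arranged
crystalline amylopectin reports starch granules, and two-photon-excited
endogenous fluorescence (EF) reports the gluten network; the gas phase is
dark in both. `gcwmorph` implements the quantitative arm of this approach:
fusing polarization-resolved backward/forward SHG into a complete
granule image, segmenting granules and the EF wall envelope, and measuring
starch areal fraction, Max-Feret size distributions with A/B/C typing, wall
dimensions (L × W × D) and the string/intact wall classification. Because
raw stacks of this kind are not publicly deposited, the package ships a
ground-truthed simulator and every stage is validated against it.

## The simulator

The simulator is a phenomenological model of the acquisition, not a
nonlinear-optics propagation code. It reproduces the features the analysis
depends on:

* **Scene.** A wall (string, intact, or bulk slab) of nominal L × W × D at
  a z-offset in the stack, optionally rotated in-plane and tapered.
  Strings have depth comparable to their width and well below the stack
  depth; intact walls span ≥ 0.9 of the stack. Ellipsoidal granules are
  drawn from a trimodal lognormal diameter mixture (modes 4/6/22 µm for
  C/B/A types, number weights 0.50/0.42/0.08) — C granules dominate counts,
  A granules dominate volume, as in wheat flour. A-type granules are
  oblate (lenticular, axial semi-axis 0.4 × equatorial), B/C near-spherical.
* **Placement.** Distance-transform-guided sequential adsorption: granules
  are placed largest-first into the free gaps of the wall footprint,
  balancing per-slice starch load across a window around mid-depth so that
  every interior slice carries a comparable areal fraction (real walls are
  not single ellipsoid layers). Placement stops when the areal starch
  fraction on the wall's central slices reaches the target (recorded
  exactly from the voxel grid, tolerance ±0.02); a target that cannot be
  reached after bounded retries raises `PlacementError`. Crowded granules
  may interpenetrate slightly — dough granules are pressed and deform —
  bounded to ≤ 30% of a granule's voxels and < 1% of the stack's voxels in
  total; contested voxels keep the first granule's label. Without this
  allowance, hard ellipsoids jam near an areal fraction of ~0.5 in thin
  walls, below what real GCWs exhibit.
* **SHG channels.** Per granule, intensity follows the two-lobe law
  `|cos(θ_radial − θ_pol)|^p` on concentric shells (default lobe exponent
  p = 2, chosen so that the four-angle sum is a uniform outline — the
  qualitative behavior that motivates summed reconstruction), zero inside
  the centrosymmetric hilum (default 25% of the granule radius). Backward
  detection is periphery-weighted and forward detection interior-weighted
  (complementary linear ramps in the normalized radius). Gluten and gas
  generate no SHG. Depth attenuation is `exp(−z/λ_SHG)`, λ_SHG = 6.5 µm,
  which reproduces analyzable depths of ~15 µm at a 10% contrast floor.
* **EF channel.** Gluten carries a band-pass-filtered noise texture
  (fibrillar appearance) at unit mean; granule interiors sit at 15% of that
  level ("empty" fluorescence objects); gas is zero. λ_EF = 40 µm, so the
  EF analyzable depth always exceeds the SHG one.
* **Artifacts.** Anisotropic Gaussian blur with lateral σ = 0.4 µm and
  axial σ = `z_elongation_factor` × lateral (default 3), the source of the
  tubular z-appearance of granules; then signal-dependent shot noise
  (sd = `noise_scale`·√intensity, default 0.02). A single integer seed
  drives scene, texture and noise through independent seed-sequence
  children; stacks are byte-identical across runs.

What the simulator does **not** emulate: refractive-index heterogeneity and
its depth-dependent aberrations, THG and its interface halo, polarization
scrambling with depth, detector offsets, or mechanical drift. Passing
tests therefore demonstrate correct recovery under this idealized optical
model, not performance on arbitrary real acquisitions.

## Reconstruction

A single polarization angle excites only shell segments nearly parallel to
it, so each SHG channel shows two lobes per granule. `combine_polarizations`
sums all SHG channels (both detection directions, all four angles; `max` is
available as a saturation-robust option) and rescales to the input dynamic
range. For p = 2 the four-angle sum of `cos²` is exactly uniform, which is
why fused outlines are complete.

`determine_analyzable_depth` gates segmentation to a contiguous slice
prefix: per-slice robust maxima (99th percentile) are compared against the
brightest slice, and the analyzable range runs from the first slice at or
above `contrast_floor` (default 0.1) of that reference through the last
consecutive such slice. Referencing the brightest slice rather than
literally the first keeps faint blur tails above the wall from defining the
baseline. On a pure exponential decay of length λ the recovered depth is
λ·ln(1/floor) to within one z-step.

`compute_anisotropy_orientation` returns the intensity-weighted
second-moment principal axis of a masked pattern in [0°, 180°); patterns
with axis ratio < 1.1 are flagged isotropic/undefined. On rendered
granules the recovered angle tracks the excitation polarization within 5°.

## Segmentation

Granules: the fused SHG field (per-slice attenuation-normalized, Gaussian
smoothed at 0.35 µm) is thresholded (Otsu by default), closed and
hole-filled per slice (the dark hilum sits inside a bright shell), and
split with a 3D marker-based watershed on the anisotropy-aware Euclidean
distance transform. Markers are the **hilum cores**: h-minima (depth 0.08
of the normalized scale) of the intensity inside the starch mask — the same
dark-center cue a human uses to separate touching granules. Small granules
whose hilum is blurred away get distance-transform peak markers (h = 0.3 µm)
at least 2 µm from any core; a blob with no marker at all falls back to one
marker at its distance maximum. Distance-transform-only markers were
evaluated first and could not separate interpenetrating granules (wide
necks carry no distance saddle).

Envelope: the wall outline is operationally a low threshold on the EF
image — just high enough to suppress the dark gas cavity. The pipeline
applies the threshold (default 0.25) to the per-slice-normalized EF (normalizer
clamped at 0.45 of the global robust max so blur-tail slices are not
amplified), then per slice: Euclidean closing at granule scale (3 µm — a
row of touching granules must not sever the outline), largest 8-connected
component, hole filling (granule interiors are dark), and a light opening.
Otsu thresholding is available but sits between the granule interiors and
the gluten texture, which makes a +40% sweep point eat into the gluten
itself; the low-cut default yields the expected few-percent sweep
sensitivity.

`interpolate_labels` reproduces the slice-skipping workflow of manual
tracing: intermediate slices are filled by per-label signed-distance
interpolation between bounding key slices; one-sided labels are copied with
a warning, and no label id absent from both bounding slices can appear.

`sweep_envelope_threshold` recomputes the envelope at threshold × (1 ± r)
(default r = 0.4) and reports the starch-fraction spread. The measurement
slices are frozen from the base envelope so the sweep isolates the outline
effect from slice repositioning.

## Morphometrics

All starch quantification is 2D, on in-plane masks — the axial elongation
artifact makes z-extents unreliable, exactly why granule volume uses the
spherical assumption V = πd³/6 on the Max-Feret diameter d. Max-Feret is
the maximum pixel-center pair distance (convex-hull reduction above 400
pixels; exhaustively verified against the all-pairs brute force). A
singleton mask is below resolution and returns 0. Size classes: C < 5 µm,
B ∈ [5, 15] µm (closed, matching the strict inequalities that define A and
C), A > 15 µm.

The size distribution is measured on one representative slice — the slice
carrying the most labels within the analyzable depth, ties going shallower
(deterministic; any interior slice with a rich granule sample is a
defensible choice). The starch
fraction is starch pixels over envelope pixels on n = 5 slices evenly
spaced across a 6 µm span, mean ± sample SD (ddof = 1). The span is placed
on the z-centroid of the segmented starch within the usable depth
(envelope ∩ SHG-analyzable), always discarding at least the first border
slice — the same "representative interior, border slices discarded"
placement an analyst applies by eye; `discard_first` can also be fixed
explicitly.

Wall dimensions: L is the Max-Feret of the mid-depth envelope slice (for a
rectangular wall this is its diagonal), W the perpendicular extent at the
L-axis midpoint (with a min/max width profile along the length, since real
walls taper), D the envelope z-extent span × z-step. Classification:
string if D ≤ 0.6 × stack depth and D ≤ 1.5 × W; intact if D ≥ 0.85 × stack
depth; anything between is flagged indeterminate and assigned by the
nearer depth ratio (boundary at 0.725).

## Numerical and design choices

* Axis order (z, y, x); slice z covers depth [z·Δz, (z+1)·Δz); defaults
  0.17 µm pixels, 0.5 µm z-step; 16-bit unsigned TIFF with a YAML sidecar,
  channel-fastest page order.
* 26-connectivity for 3D labels, 8-connectivity in-plane.
* Morphological closings/openings at physical radii use two distance
  transforms (exact Euclidean disks) rather than large structuring
  elements.
* Watershed determinism: markers are labeled in scan order from
  deterministic inputs; the whole pipeline is reproducible bit-for-bit
  given the stack.
* Validation scenes are 256 × 256 px × 48 slices (43.5 × 43.5 × 24 µm) —
  the acquisition geometry scaled to a quarter field of view, with walls sized
  so strings and intact walls keep their defining depth ratios. The
  simulator's default canvas remains the full 1024 × 1024 × 84 acquisition
  format.

## Known limitations

* At areal packings ≥ 0.55 in thin walls, interpenetrating granules form
  genuinely fused bodies; per-granule counts and IoU degrade there (counts
  recover within ~15% at moderate packing ≈ 0.45). Areal starch
  quantification is unaffected — verified across the full 0.30–0.65 grid.
* The axial blur model cannot reproduce arbitrarily strong tubular
  elongation: the half-max z/xy aspect of a blurred 10 µm sphere
  approaches the σ ratio only when σ is comparable to the radius (≈1.6 at
  an exaggerated 2.5 µm PSF, factor 2).
* z-stacked granules closer than the axial blur length fuse; this mirrors
  the real z-resolution limit that confines the quantification to 2D
  analysis.
* The envelope assumes one wall per field of view (largest component);
  multi-wall scenes are out of scope.
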