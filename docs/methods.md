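# Methods

This note documents the models, parameter choices, and numerical
conventions behind `teaprof`, and what the synthetic-canopy tests do and do
not establish about field behaviour.

## Scene model and what the generator emulates

The generator (`teaprof.synthetic`) renders a nadir view of a bulk-tea
canopy top as:

- **Geometry.** A one-dimensional arc swept down the image:
  `depth(x) = peak + sag·u² + tilt·t` (cm), with `u ∈ [−1, 1]` the
  normalized offset from the centre column and `t ∈ [−0.5, 0.5]` the
  normalized column. Defaults: peak 45 cm (the ideal centre depth
  `a_near − L` for the default rig), sag 6 cm, tilt 0. Old-leaf pixels sit
  a further 8 cm from the camera (`old_leaf_depth_offset`), which is what
  makes mask-conditioned depth averaging matter.
- **Shoot layout.** Overlapping rotated ellipses stamped until coverage
  reaches `shoot_density` (default 0.8). Semi-axes 12–26 × 7–15 px; at the
  default 320-px width the camera footprint implies roughly 5 px/cm, so
  these are 5–10 cm clusters of stacked shoots. Bulk shoots blanket the
  canopy top in large contiguous patches rather than isolated sprigs; the
  coverage and cluster scale encode that. Densities ≥ 0.999 mean "all
  shoot", which turns the regional ground truth into an exact integral of
  the arc (used by the numeric-integration oracle test).
- **Colour.** Shoots: `G = 190·jitter`, `R = 0.45·G`, `B = 0.35·G`
  (per-blob jitter 0.88–1.05). Old leaves: the same hue darkened by 0.45
  and modulated by a leaf texture that is deliberately dominated by
  per-pixel speckle (σ = 8%) over a gentle low-frequency field (±3%): leaf
  surfaces are locally rough, so background contrast lives at the pixel
  scale, where a small erosion can remove it, rather than in large
  connected patches. Shoot pixels always satisfy `G > R, B` before
  illumination scaling.
- **Illumination.** A single multiplicative gain found by deterministic
  bisection (60 iterations on [0.05, 8]) so the rendered frame's AG lands
  at 120 (low preset) or 168 (high preset), mid-band values matching field
  frames recorded under overcast (AG 115–124) and sunny (166–171) skies.
  Specular patches, when requested, are small ellipses saturated at 248 in
  all channels and are excluded from the ground-truth mask (a highlight
  destroys the colour evidence a segmenter could use).
- **Depth noise.** Gaussian, σ = 3 mm by default, rounded to integer mm
  (uint16), plus a `hole_fraction` of invalid (0 mm) pixels. Ground-truth
  `l` values are computed from the noise-free surface, so quantization
  alone separates a perfect estimator from truth (≤ 0.05 cm).

**What passing tests do not show:** the generator has no occlusion
ordering, no per-leaf shading or specular gradients, no lens distortion or
motion blur, and only the nadir (90°) mount geometry. Segmentation scores
on it demonstrate the pipeline's internal consistency and its behaviour
under the documented invariants, not field accuracy.

## Segmentation conventions

- Super-green index read as `2G − (R/2) − B`, computed in floating point,
  clamped to [0, 255], then quantized half-away-from-zero to uint8.
- AG uses BT.601 luma weights (0.299, 0.587, 0.114) over the whole frame;
  the camera is aimed so the canopy fills the frame. An optional region
  restricts it.
- Lighting bands: [90, 140) low, [140, 220] high; 140 belongs to high.
  AG outside both bands raises an error rather than guessing a branch —
  behaviour is only defined inside the bands — but the caller can force a
  branch explicitly.
- CLAHE is implemented in-package with the tile-LUT + bilinear-blending
  algorithm and the clip limit expressed as a multiple of the mean
  histogram bin count (clip 2.0, 8×8 tile grid, applied to the YCbCr luma
  with chroma carried through). The scikit-image implementation uses a
  different clip-limit scale and renormalizes the CDF so that even a flat
  tile is stretched to full range, which contradicts a finite clip limit;
  the in-package version keeps a constant image (approximately) constant.
- Specular rule: minimum channel ≥ 230 (a saturated highlight is bright in
  all channels). The threshold is configuration, not a measured constant.
- Otsu: exhaustive maximization of between-class variance over all 256
  thresholds (vectorized); ties break toward the lower threshold. With
  `exclude_zero` the zero bin is removed so zeroed specular pixels cannot
  influence the split; foreground is the bright class (`Ḡ > t`).
- Erosion: 3×3 square, 1 iteration by default; border treated as
  background, so masks shrink at frame edges.
- The high-light branch does not apply CLAHE; the processing sequence
  treats contrast enhancement and specular suppression as alternatives
  selected by the lighting class.

## Depth conventions

- Units: rasters in mm (uint16, 0 = invalid sentinel); the `l_near`/`l_far`
  interface is in cm.
- Gate default [200, 2000] mm — wide margins around the 450–750 mm
  camera-to-canopy distances of the reference rig. Median kernel 5;
  windows use valid pixels only and invalid pixels stay invalid.
- Region fractions map to pixels as `floor(frac·extent)`, half-open, so
  pixel counts are reproducible at any resolution. Defaults: near = columns
  4/14–10/14 × rows 3/8–5/8, far = columns 1/14–2/14 × rows 3/8–5/8.
- A region needs ≥ 25 valid shoot pixels; otherwise the whole-region
  valid-pixel mean is used and flagged (`fallback`) — the machine must
  still produce a pose every frame — or an error is raised when fallback
  is disabled.

## Pose and kinematics

- Sign conventions: `d > 0` raises the cutter; `α > 0` rotates the left end
  down toward the canopy (consistent with `α`'s formula: `l_far` larger
  than ideal ⇒ positive α).
- Default rig: `a_near = 55`, `a_far = 61`, `L = 10`, `r = 114` cm. `r` is
  a documented default back-derived from the reference rig's angle-error
  scaling (180/(r·π) ≈ 0.5026 deg/cm); `b = 40`, `m = 10`, `c_zero = 80` cm
  are placeholder deployment measurements satisfying the linkage's triangle
  inequality. All are overridable in `RigConfig`.
- `Δx` is solved in closed form: θ₀ = arccos((b²+r²−c²)/(2br)),
  θ₁ = θ₀ + α, `Δx = √(b²+r²−2br·cos θ₁) − c`, with θ₁ required to stay in
  (0, π) and the arccos argument in [−1, 1] (mechanism-limit errors
  otherwise). A numeric root-finder on the forward model serves as a test
  oracle only.
- The angle formula treats the height move and the rotation as independent
  per-frame corrections; it ignores that applying `d` also translates the
  left end. This is an approximation inherited from the control design, and
  it is why the closed loop converges in one step only when the height
  error is small (`0 ≤ d < far-band half-width`). The `VirtualCutter` test
  model encodes the camera riding and tilting with the cutter:
  `l_near += d`, `l_far += d − r·α·π/180`.
- Decision table: two partitions (near: [35,43) rise / [43,47) hold /
  [47,55) fall; far: [43,51) / [51,55) ideal / [55,63)) and a complete 3×3
  grid — plus per-axis out-of-range, giving the ten motion types. The
  rotation in each cell follows the left end's deviation *relative to* the
  centre's (`far_class − near_class`): a cutter that must rise while its
  left edge reads ideal will overshoot on the left after rising, hence
  (rise, rotate_down). Only the no-operation cell and that combined case
  are fixed by the reference design; the remaining cells are mirrored
  complements, and the whole table is a JSON-configurable deployment
  artifact. When one axis is out of range the other axis' decision is
  taken from the hold row/column of the grid.

## Metrics conventions

- Confusion counts are pixel-level; instance-level shoot separation is a
  non-goal (the mask only feeds depth averaging).
- Trial aggregation uses the population (divide-by-n) standard deviation —
  the convention that reproduces the reference field-trial table — and
  half-away-from-zero rounding at the printed precision.
- Multi-trial productivity sums areas and times before dividing
  (`ΣA/(ΣT·B)`); it is not the mean of per-trial productivities.
- "Tea making rate" has no defining formula and is supported only as
  user-supplied values for aggregation.

## Problem sizes

Tests and examples run on 320×240 frames (single-frame generation ≈ 0.2 s,
full pipeline ≈ 0.4 s); the Otsu oracle check uses 200 random 64×64 images
and the linkage round-trip a grid of ~150 (b, r, c, α) combinations. These
sizes exercise every code path at full fidelity; nothing in the
implementation is resolution-dependent beyond the region-fraction mapping.

## Known limitations

- The segmentation assumes the canopy fills the frame; rows of sky or
  machinery in view would distort AG and the Otsu histogram.
- The erosion-based cleanup trades recall at shoot-cluster boundaries for
  precision; with the default 3×3 kernel the synthetic recall settles near
  0.91 (precision 1.0) at 320×240 — higher resolutions lose less boundary.
- One-step closed-loop convergence is an approximation property, not a
  guarantee; large simultaneous height and tilt errors need a second
  iteration.
- The decision table's non-printed cells are design choices; deployments
  should calibrate their own band edges to their canopy and cutter.
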