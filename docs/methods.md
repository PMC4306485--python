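# Methods

## Problem and quantity of interest

Labial minor salivary glands (LSGs) of the lower lip are imaged *in vivo* by
swept-source OCT as hypointense foci embedded in the highly reflective
muscular layer, each normally connected to the mucosal surface by a narrow
hypointense excretory duct. The quantity this package computes is the **LSG
surface density**: the number of accepted glands divided by the useful imaging
surface (glands/cm²). Two cohorts of 18 subjects each are compared with a
two-sided Mann–Whitney U test.

The counting rule is: an interior hypointense focus counts as a gland only if
an excretory duct can be matched to it; a focus at the border of the useful
surface is counted without a duct match, because its duct may lie outside the
field. The density denominator is always the configured useful-surface
constant (2.43 cm²), never the pixel-counted mask area, so a count of 10 maps
to 10/2.43 = 4.12 glands/cm² exactly.

## Synthetic phantom

Because raw clinical volumes are not distributed with the package, every stage
is exercised on a synthetic SS-OCT phantom with exact ground truth. Per voxel
at depth `d` µm below the local surface:

```
I = R(layer(d)) · exp(−µ·d) · C · S + N,   clipped at 0
```

- `R`: layer reflectivity — epithelium 0.4 to 300 µm, connective tissue 0.7
  to 600 µm, muscle 1.0 below (arbitrary units). The boundaries and ratios
  are plausibility choices that reproduce the visual layering of labial
  mucosa; no published values exist for this instrument.
- `µ`: attenuation, default 0.8 mm⁻¹ (soft-tissue scale at 1310 nm).
- `C`: `gland_contrast` = 0.25 inside gland ellipsoids and duct cylinders,
  1 elsewhere. Glands are hypointense, so `C ∈ (0,1)` is enforced.
- `S`: unit-mean exponential multiplicative speckle (fully developed speckle
  intensity statistics; a single-parameter model).
- `N`: zero-mean Gaussian detector noise, SD 0.01.

The surface is a plane (default 400 µm offset, 60/40 µm·cm⁻¹ tilt) plus a
quadratic bulge (150 µm at the field corners), emulating the residual
curvature left by the glass plate. Glands are axis-aligned ellipsoids defined
in depth-below-surface coordinates, so they drape with the interface. Ducts
are vertical cylinders (radius 30 µm) from the surface to the gland top at
the gland's lateral centroid. Because 30 µm is below the lateral pitch
(43 µm at 400×400; 135 µm at the reduced raster), the generator always
renders at least the A-scan column nearest the duct axis at full contrast: a
beam passing through a sub-pitch duct sees the full shadow, which is exactly
what makes ducts recognisable at the instrument's sampling density.

Default scan geometry: 400×400 A-scans over 1.73×1.73 cm², 3.4 mm depth
range, 50,000 A-scans/s, 1310 nm centre wavelength, ~100 nm tuning range.
`n_depth` defaults to 512 (≈6.6 µm axial pitch, on the scale of the 6.7 µm
axial resolution); the per-A-scan sample count of the original instrument is
not public.

### Cohort presets

Two fixed 18-subject presets define the study conditions. Their per-subject
gland counts are

- lower-density ("CF-like"): 5 6 7 7 8 9 10 10 10 11 12 13 14 15 15 16 17 18
  (median 10.5 → 4.32 glands/cm²),
- higher-density ("HS-like"): 10 11 12 13 14 14 15 16 16 16 17 18 19 20 20 21
  22 23 (median 16 → 6.58 glands/cm²),

so that with perfect detection the group density medians land on the values
the method is meant to report. All preset glands carry ducts and are placed
by rejection sampling inside the useful surface, clear of its border, with a
1.9 mm minimum centre-to-centre spacing; subject seeds are `base_seed + i`.
Preset glands use lateral semi-axes U(400, 700) µm and axial semi-axes
U(300, 450) µm at 750 µm centre depth. The module-level default for ad-hoc
phantoms is broader (U(500, 900) µm); the preset range is narrower because at
23 glands the broader sizes would sit near the geometric packing limit of the
2.43 cm² surface at non-overlap spacing, making placement unreliable, while
0.8–1.4 mm footprints remain typical of labial glands.

## Processing chain

1. **Surface segmentation.** The noise floor is estimated from the shallowest
   5 % of depth samples; the surface in each A-scan is the first sample above
   `mean + 4·SD` of that noise. Positions with no crossing are in-filled from
   the nearest valid neighbour; positions deviating from their 5×5 window
   median by more than two voxels are replaced by it (outlier repair that
   leaves exact maps untouched). If the shallow samples are bright relative
   to the volume median, the volume is already surface-aligned and the map is
   identically zero — this is what makes flattening exactly idempotent. If
   over half of the A-scans have no crossing the volume is rejected as empty.
2. **Flattening.** Integer per-A-scan shifts (axial pitch ≈ axial resolution,
   so sub-voxel interpolation would add cost without information); vacated
   deep voxels are zero-filled. Intensities are relocated, never altered.
3. **En-face projection.** Mean intensity over a 100 µm slab centred at
   750 µm below the flattened surface.
4. **Useful surface.** A centred disc clipped by the scan square whose
   pixel-counted area equals 2.43 cm² to within one pixel; the radius is
   solved on the monotone pixel-count curve with a deterministic raster-order
   tie-break for the 4/8-fold symmetric boundary pixels.
5. **Focus detection.** The C-scan is Gaussian-smoothed at 150 µm (well below
   the minimum gland radius, enough to suppress residual slab speckle),
   normalised by the in-mask median, log-transformed, and split by Otsu's
   threshold within the mask. The split is only trusted when the two class
   means separate by ≥ 0.7 log units; otherwise the projection is declared
   gland-free. This guard is what prevents Otsu from splitting pure speckle
   in low-count or gland-free fields. The dark class is cleaned by a
   radius-1 binary opening, labelled with 8-connectivity, and gated to
   footprints of 0.1–5 mm². A component within 1 px of the mask edge is a
   border focus.
6. **Duct matching.** For each focus, the gland-top depth is estimated as the
   first depth at which the footprint-mean profile falls below half the
   background ring profile (ring beyond both twice the search radius and the
   footprint radius). A duct is declared when any A-scan column within 150 µm
   (at least two pixels) of the centroid is darker than 0.6 × the ring
   background over the span from just below the surface (50 µm) to the gland
   top. The search radius, intensity ratio and the 50 µm offset are
   calibration choices validated against phantom ground truth.
7. **Counting and density.** `accepted = has_duct OR on_border`; density =
   accepted count / 2.43 cm².

## Statistics

- **Mann–Whitney U**: midranks for ties; exact p by full enumeration of all
  `C(n_x+n_y, n_x)` labelings when both groups have ≤ 8 observations (valid
  under ties), otherwise the normal approximation with tie-corrected variance
  and a 0.5 continuity correction. Two-sided throughout. Across all 924
  tie-free 6-vs-6 rank arrangements the approximation stays within 0.02 of
  the exact p (tested exhaustively).
- **Quartiles**: linear interpolation between order statistics (the common
  "type 7" convention); medians are the primary endpoint, quartile
  conventions differ across software so IQRs should be compared loosely.
- **ICC**: ICC(2,1) — two-way random effects, absolute agreement, single
  measures — from the ANOVA mean squares
  `(MS_R − MS_E) / (MS_R + (k−1)MS_E + k(MS_C − MS_E)/n)`. This is the
  standard form for rater-reproducibility studies; it is cross-checked
  against `pingouin`'s ICC(A,1) to 1e-10 in the test suite.
- **Sample size**: the two-sample normal-approximation formula
  `n = ⌈2 (z₁₋α/₂ + z_power)² σ²/δ²⌉`; at δ = 30, σ = 30, α = 0.05,
  power = 0.84 this gives n = 18 per group.

## Problem sizes and determinism

The cohort experiments in the tests and in `scripts/acceptance.py` run at a
128×128×256 raster over the same physical field. Gland counts are
resolution-independent by construction (glands span many pixels at either
pitch), so the reduced raster reproduces the ground-truth counts — and hence
the medians and the rank-sum p — exactly; this is asserted, not assumed. A
full-resolution subject (400×400×512) takes ~15 s to simulate and process and
is covered by the same code path.

Equal configs (including seed) produce bit-identical volumes; cohort subject
seeds derive from the run seed, and summary JSON is byte-stable across
repeated runs of the same config.

## What the phantom does and does not show

Passing on the phantom demonstrates that the geometry, projection, counting
rule, and statistics are implemented correctly and that detection is robust
to fully developed speckle, depth attenuation, surface tilt and bulge. The
phantom does **not** model: coherent point-spread-function effects,
polarisation, motion between B-scans, anatomical variation in gland shape or
duct course (ducts are straight and vertical), partial-volume texture of real
glandular lobules, or operator variability. Observer-agreement ICC values
from the original counting protocol (0.89 intra-, 0.80 inter-observer) and
the clinical study's exact p-value and IQRs are properties of the human
annotation data and are not reproducible from synthetic volumes; the package
instead verifies the estimators themselves against independent closed-form
oracles.

## Known limitations

- First-crossing surface segmentation assumes the interface lies below the
  shallowest 5 % of samples (true for the glass-plate geometry emulated
  here); volumes whose tissue starts at the very first sample are treated as
  already flattened.
- Otsu-based focus detection needs the gland class to occupy roughly ≥ 1 % of
  the useful surface after smoothing; isolated sub-0.1 mm² foci are below the
  area gate by design.
- The duct detector assumes near-vertical ducts; strongly oblique ducts would
  require a path search rather than a column test.
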