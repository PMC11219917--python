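# Methods

## Model

The estimator treats the eyeball as a convex, approximately spherical solid
sampled by parallel axial sections. Each binary mask slice is summarized by
its equivalent-circle radius r = sqrt(S/pi), where S is the physical
foreground area; the solid between adjacent slices is modeled as a
truncated cone (frustum) with those two radii, so the mid-section volume is
the sum of N-1 frustum slabs. Two baselines share the same profile: the
truncated-cylinder sum (each slab uses only the lower-index slice's radius)
and the raw pixel-count sum (slice area times following gap). Because the
equivalent radius is *defined* from the measured area, pi*r_i^2 equals S_i
exactly and the cylinder and pixel-count baselines coincide whenever both
are computed from the same measurements; they separate only if areas and
radii are supplied independently (e.g. a fitted rather than equivalent
radius).

Terminal slices where the globe is barely visible are excluded before
stacking, so every stacking method under-covers the poles. The correction
treats the globe as a sphere whose radius is the largest equivalent radius
m in the profile and adds, per end, the spherical cap beyond the terminal
kept slice: V_cap = pi * (2m^3/3 - m^2 x1 + x1^3/3), the closed form of
pi * Int_{x1}^{m} (m^2 - x^2) dx.

Two cap modes are implemented because the integration bound can be read two
ways. In `geometric` mode (default) x1 = sqrt(m^2 - r_end^2), the axial
coordinate of the cutting plane through the terminal slice, which makes
each cap exactly the sphere segment cut off at that slice; each end uses
its own terminal radius. In `literal` mode both caps share
x1 = min_i r_i, treating the smallest slice radius itself as the bound.
`geometric` is the default because it is the geometrically consistent
reading — integrating pi*(m^2 - x^2) from a *radius* only measures a cap
when x is an axial coordinate — and on sphere phantoms it recovers the
analytic volume to well under 1%. The mode is recorded in every output row.
A flat profile (terminal radius equal to the maximum) would imply
hemisphere caps; this violates the sphericity assumption and triggers a
warning.

Edge conventions: all-zero profiles are rejected; x1 is clamped to [0, m];
the closed form returns exactly 0 at x1 = m and clamps the sub-ulp negative
residue of floating-point cancellation. Volumes accumulate in mm^3 with
compensated summation (`math.fsum`); conversion to cc (1000 mm^3) happens
only at reporting, rounded to 3 decimals.

## Measurement conventions

The pixel count A is the *sum* of foreground pixels, and the physical area
is S = A * p_h * p_w; a mean over the raster would be a dimensionless
fraction and could not yield an area. Likewise the equivalent radius is
r = sqrt(S/pi) — the inverse form sqrt(pi/S) would shrink with growing
area. Binarization thresholds at half the dtype's maximum representable
value (0.5 for floats), which keeps exact binary masks intact, tolerates
anti-aliased exports, and is idempotent: rasters already valued in {0,1}
pass through unchanged.

Inter-slice gaps h_i are successive differences of slice positions from the
DICOM headers, not the declared slice thickness, because position
differences remain correct for non-contiguous series; thickness is only a
fallback (with a warning) when positions are absent. Non-uniform pixel
spacing or duplicate positions are hard errors.

Left/right eyes are separated by 26-connected 3-D components, keeping the
two largest and discarding components below 1% of the largest as noise.
Laterality comes from the centroid column relative to the image midline
(image-left = smaller column); radiological left/right additionally depends
on patient orientation metadata, which the caller must supply.

## Slice selection

A slice is kept when its equivalent radius reaches `min_radius_fraction`
(default 0.35) of the stack maximum; interior dropouts are re-included so
the selection is contiguous, and the counts of excluded terminal slices are
reported to the cap correction. At the default fraction a sphere loses
roughly the outermost 6% of axial extent per end. The fraction is a free
parameter: clinical practice selects visible slices manually, and no single
number reproduces that judgement, so the default is a package choice and is
configurable everywhere (`--min-radius-fraction`).

The default display window (center 40 HU, width 400 HU) is a standard
soft-tissue window covering vitreous (~0-20 HU) and sclera; windowing is
provided for preview and QC only — all measurement operates on masks.

## Phantoms

The generator digitizes spheres and ellipsoids: a voxel is foreground iff
its center lies inside the surface, exactly what a hard segmentation mask
provides (no partial-volume values). Defaults are at human scale: radius
12 mm (7.24 cc), pixel 0.5 mm, gap 1 mm. Boundary jitter perturbs the
in-plane boundary radius independently in 16 angular sectors per slice by
N(0, sigma) pixels, emulating ragged segmentation edges while preserving a
roughly correct area. End-slice exclusion applies the same visibility rule
used in the pipeline. Every stack carries its analytic volume
(4/3) pi a b c.

Cohorts sample radius uniformly on 10-14 mm, gap on 0.8-1.5 mm and
exclusion fraction on 0.25-0.45, with jitter sigma 0.5 px — a spread wide
enough that the method ordering is tested across realistic acquisition
variation, not at one lucky configuration. The reference volume defaults to
the exact analytic volume; optional N(0, noise^2) cc observation noise can
emulate inter-observer variability in manual volumetry, but no published
value anchors its magnitude, so the default is 0 and the parameter is
explicit. One master seed spawns per-phantom seeds, so each phantom is
reproducible in isolation.

What the phantoms do **not** emulate: real CT texture and noise, the lens
and optic nerve, partial-volume boundaries, oblique acquisitions, and
systematic segmentation bias (a model that consistently over- or
under-segments). Passing tests therefore demonstrate the correctness and
ordering of the volumetry formulas under controlled geometry, not clinical
segmentation accuracy.

## Evaluation

Paired comparison reports Pearson correlation (Spearman available), mean
absolute error (cc), mean squared error (cc^2), and Bland-Altman agreement:
mean difference of estimate - reference with limits of agreement at
+/- 1.96 sample standard deviations (n-1). Zero-variance inputs make the
correlation undefined and it is reported as NaN, never 0. Dice and IoU use
the convention that two empty masks score 1.0 (perfect agreement on
absence). Box-plot summaries use linearly interpolated quartiles and Tukey
whiskers at 1.5 IQR; errors are signed reference - estimate by default,
with an `--absolute` option.

## Problem sizes and numerical checks

Digitization error oscillates with the sub-voxel alignment of the body
against the grid, so convergence studies (and the disc-radius convergence
test) average absolute error over a handful of seeded sub-voxel placements
per refinement level; single placements can show non-monotone error purely
from alignment luck. The refinement ladder uses pixel sizes 1.0/0.5/0.25 mm
with gap = 2x pixel and 8 placements per level; the method-comparison
cohort uses 50 phantoms at 0.5 mm pixels. Both finish in seconds on one
core while leaving the discretization trends well resolved. Closed forms
(frustum slab, spherical cap) are verified against adaptive quadrature of
the corresponding solids of revolution to 1e-9 relative tolerance.

## Known limitations

* The sphericity assumption is structural: on ellipsoids the cap-corrected
  error grows monotonically with aspect ratio (documented by test), and
  pathological globes (staphyloma, TED) will inherit that bias.
* Equivalent-radius reduction discards cross-section shape; no sub-pixel
  (marching-squares) boundary estimation is attempted.
* Only single-frame axial DICOM series are supported; multi-frame/enhanced
  DICOM and oblique stacks are out of scope.
* Laterality from image columns is a heuristic; orientation metadata is not
  interpreted automatically.
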