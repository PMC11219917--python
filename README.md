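# ocuvol

Eyeball volumetry from CT segmentation masks.

Clinicians monitor myopia progression and other ocular disease through
eyeball volume, but manual volumetry on CT is slow and observer-dependent.
Given per-slice binary masks of the globe (from any segmentation model) and
the scan geometry from the DICOM headers, `ocuvol` estimates the eyeball
volume with a method that respects the organ's shape, alongside the two
standard pixel-based baselines, and ships a synthetic phantom generator so
every stage can be validated without patient data.

## The estimator

Each axial mask slice *i* is reduced to its foreground pixel count
*A<sub>i</sub>*, physical area *S<sub>i</sub> = A<sub>i</sub> ·
p<sub>h</sub> · p<sub>w</sub>* (mm²), and the equivalent radius of the
circle with the same area, *r<sub>i</sub> = √(S<sub>i</sub>/π)* — axial
cross-sections of the globe are nearly circular. With inter-slice gaps
*h<sub>i</sub>* (successive differences of slice positions), three
mid-section estimates are available:

| method | per-slab volume |
|---|---|
| pixel count | *S<sub>i</sub> · h<sub>i</sub>* |
| truncated cylinder | *π r<sub>i</sub>² h<sub>i</sub>* |
| truncated cone (frustum) | *(π h<sub>i</sub>/3)(r<sub>i</sub>² + r<sub>i</sub>r<sub>i+1</sub> + r<sub>i+1</sub>²)* |

summed over the *N−1* slabs. Because terminal slices with a barely visible
globe are excluded before measurement, all three miss the poles. Modeling
the globe as a sphere of radius *m* = max<sub>i</sub> *r<sub>i</sub>*, the
missing end volume is the spherical cap beyond the terminal slice,

&nbsp;&nbsp;&nbsp;&nbsp;*V<sub>cap</sub> = π ∫<sub>x₁</sub><sup>m</sup> (m² − x²) dx
= π (2m³/3 − m² x₁ + x₁³/3)*,&nbsp;&nbsp; *x₁ = √(m² − r<sub>end</sub>²)*,

computed per end and added to the frustum sum (the default `geometric` cap
mode; a `literal` mode that uses the smallest slice radius directly as the
integration bound is also provided). The full pipeline is: split the mask
volume into left/right eyes by 3-D connected components → crop → measure →
select visible slices → stack → cap-correct.

## Worked example

Generate a digitized 12 mm sphere phantom (true volume 7.238 cc) with
terminal-slice exclusion, then estimate its volume:

```sh
$ ocuvol phantom --radius 12 --pixel 0.5 --gap 1.0 --exclude 0.35 --seed 7 --out subjects/s000
wrote 22 mask slices to subjects/s000 (analytic volume 7.238 cc)

$ ocuvol estimate --masks subjects --method cone --caps geometric --out est
subject_id     eye         method  cap_mode  mid_volume_cc  cap_volume_cc  total_cc
      s000 unknown cone_plus_caps geometric          7.076          0.169     7.245
```

The frustum stack over the 22 kept slices contributes 7.076 cc, the two
spherical caps restore the 0.169 cc lost at the poles, and the total of
7.245 cc is within 0.1% of the analytic 7.238 cc. Comparing all three
methods over a 50-phantom cohort with boundary jitter and varying exclusion:

```sh
$ ocuvol compare --n 50 --seed 7 --out cmp
        method     corr      mae      mse  n  mean_diff  loa_lower  loa_upper
   pixel_count 0.999370 0.194161 0.044781 50  -0.194161  -0.360786  -0.027535
      cylinder 0.999370 0.194161 0.044781 50  -0.194161  -0.360786  -0.027535
cone_plus_caps 0.999944 0.027673 0.001133 50  -0.024964  -0.069649   0.019721
```

The cap-corrected frustum method cuts the mean absolute error roughly
seven-fold, and its Bland–Altman mean difference sits closest to zero: the
baselines systematically underestimate because they ignore both the
curvature between slices and the excluded ends. (Pixel-count and cylinder
stacking coincide whenever radii are derived from the measured areas, since
then *π r<sub>i</sub>² = S<sub>i</sub>* identically.)

Other subcommands: `ocuvol evaluate` (compare an estimate table against
reference volumes, with optional per-group box-plot summaries) and
`ocuvol window` (HU-windowed previews of a DICOM series). Each run writes a
`manifest.json` recording configuration, versions and seeds.

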