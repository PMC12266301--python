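# Methods

This note records the model, the conventions and the design decisions
behind `facedefender`, in enough detail to reproduce or audit any
number the package computes.

## Coordinate and laterality conventions

All coordinates are 0-based pixels with the origin at the top-left
corner, x rightward and y **downward**; landmark coordinates are floats
at pixel centers. Angles in this frame are clockwise-positive on
screen: the interocular axis is the signed angle of the vector from the
left-eye iris center to the right-eye iris center, in (−180°, 180°].

Landmark group names (`LEFT_*`, `RIGHT_*`) are **image-side**: the left
eye is the one at smaller x. On a frontal photograph the image-left eye
is the subject's anatomical right eye; diagnostic outputs are relabelled
anatomically by default (`laterality` config), because clinical
strabismus labels are anatomical. Keeping the geometry layer image-side
and converting only at the reporting boundary avoids double-flips.

The 52 periocular landmarks split 26 per eye: 16 eyelid points ordered
to trace a closed contour, 5 iris points whose centroid is the iris
center, and 5 brow points. Anatomical roles (medial/lateral canthus,
lid apices, brow apex) are resolved geometrically on the aligned face —
medial = eyelid point nearest the facial midline, apices = vertical
extremes — rather than by fixed indices, so any detector that emits the
six groups works without an index contract. This resolution assumes an
approximately roll-corrected face; the alignment step guarantees that,
and the quality gate rejects rolls above 5°.

## Fusion pipeline

Preprocessing rotates the image rigidly about the iris midpoint until
the interocular axis is horizontal (bilinear resampling, white fill)
and places it on a square white canvas — padding centers the content,
cropping centers on the iris midpoint with the window clamped inside
the source; no rescaling, so pixel distances are preserved exactly.

Per eye, the transplant transform is the least-squares map from the
patient's 26 periocular landmarks to the avatar's. The default
constraint is a **similarity** (uniform scale × rotation + translation,
solved in closed form by the Umeyama/Procrustes method, reflections
excluded): it preserves all length ratios, which is what makes
distances measured on the fused image interpretable — they equal
`scale_factor ×` the patient distance identically, whatever the fit
residual. A general affine (normal equations) is available by config
for detectors with anisotropic bias. Transforms are fitted
independently per eye; a single global transform cannot reconcile
patient/avatar interocular-distance mismatch without distorting one
eye.

The ROI is the convex hull of the 26 per-eye landmarks — a hull cannot
self-intersect whatever order the detector emits points in — dilated
outward along vertex normals by `roi_margin`. The warped patient image
is harmonized by per-channel mean/std transfer where both statistics
are measured on the **same annulus** (`skin_ring_width`, default 15 px)
just outside the warped ROI: the gain/offset compares patient skin with
avatar skin and is then applied to the patch, leaving the iris/sclera
contrast intact and making self-fusion an identity. (Transferring the
ROI-interior statistics onto the skin ring instead would bleach the
eye; this was checked and rejected.) Channel statistics use the
population (n) standard-deviation convention; channels with source std
below 1e-6 get unit gain.

The binary ROI mask is feathered with a Gaussian (kernel truncated at
3σ, side `2·ceil(3σ)+1`, reflect padding) and composited as
`α·patch + (1−α)·avatar`, rounded half-to-even so outputs are
byte-reproducible across platforms. Wherever α = 0 the output is
byte-identical to the avatar — that equality is the privacy contract
and is asserted in the tests. Overlapping left/right feathered regions
raise an error rather than silently blending.

Defaults `roi_margin = 8`, `feather_sigma = 6` target ~1024 px
face photographs. Feather support (3σ) should stay at or inside the
margin so the palpebral region composites at full opacity; for the
320 px schematic faces used in the test experiments the matched setting
is `roi_margin = 13`, `feather_sigma = 4`, and the distance-preservation
experiments use it for exactly that reason (with a smaller margin the
avatar's own iris bleeds through the sub-unity alpha near the lower lid
and biases the measured centroid by ~1 px).

## Distance measures and benchmarks

Per eye, measures are absolute per-axis distances from the iris center
to: medial canthus (x; named A for the left eye, B for the right),
lateral canthus (x; CD/EF), upper-lid apex (y; GH/IJ — an MRD1 analog),
lower-lid apex (y) and brow apex (y). Derived face-level measures are
the horizontal asymmetry |A−B| and the absolute vertical iris-height
difference. The letter naming and role mapping are a configurable
schema, not a fixed contract.

Benchmark construction per measure:

1. **Outlier exclusion**: single-pass (not iterated) Tukey filter,
   quartiles by linear interpolation between order statistics, keeping
   values in [Q1 − 1.5·IQR, Q3 + 1.5·IQR] inclusive. The inclusive
   bounds make a zero-IQR (constant) sample keep everything.
2. **Normality**: Shapiro–Wilk at α = 0.05; a constant sample is
   declared non-normal by convention (the statistic is undefined).
3. **Interval**: normal theory when normal — mean ± z·s (reference
   range) or mean ± z·s/√n (CI of the mean), exact normal quantile —
   otherwise a seeded bootstrap: percentile bootstrap of the mean for
   the CI mode, and for the reference range the (1∓level)/2 empirical
   quantiles of each resample averaged over B = 2000 resamples.
   Per-measure seeds derive deterministically from the fit seed.

Two interval modes exist deliberately. A CI of the mean shrinks with
cohort size and says nothing about individuals; classification needs a
population interval, so `reference_range` is the classification default
while `ci_mean` is retained for cohort reporting. In a Gaussian healthy
cohort the per-eye measures take normal-theory intervals while the
folded asymmetry magnitudes are right-skewed and route to the
bootstrap — the pipeline exercises both branches by construction.

## Classification

Per eye, one primary label from {normal, esotropia, exotropia,
vertical_strabismus, ptosis}; ptosis may also appear as a secondary
flag when strabismus takes the primary slot.

- **Horizontal strabismus**: |A−B| above the *upper* bound of its
  interval (asymmetries are folded magnitudes, so only large values are
  abnormal), attributed to the eye whose medial-canthus distance
  deviates more from its interval midpoint, *and* that distance must
  itself be outside its two-sided interval. A reduced medial distance
  means the iris deviated nasally → esotropia; increased → exotropia
  (`nasal_direction` flips the sign convention for schemas anchored on
  the lateral canthus).
- **Vertical strabismus**: vertical height asymmetry above its upper
  bound, with *both* the deviating eye's upper-lid and lower-lid
  distances abnormal — a displaced iris shifts both lid gaps in
  opposite directions, whereas lid droop changes only the upper gap, so
  this is what separates vertical deviation from ptosis.
- **Ptosis**: iris-to-upper-lid distance below its interval's lower
  bound (one-sided: droop can only reduce an MRD1 analog).

The double gates control the individual-level false-positive rate: with
95% reference ranges, single-gate screening would flag ≈12% of healthy
eyes; requiring the corroborating per-eye measure brings the expected
per-eye rate under 7% (measured ≈4–5% in the seeded experiments) at no
material sensitivity cost — an injected offset of 3× the measure's
interval half-width is detected in ≥95% of cases, the misses being
subjects whose two baseline distances are coincidentally both small so
the asymmetry stays sub-threshold.

Sample-size formulas are E = z·σ/√n and n = (z·σ/E)². The default
`z_policy="rounded"` uses the conventional two-decimal critical value
(1.96 at the 0.95 level), which is what makes reported two-decimal
values like E = 0.92 and n = 59.81 reproduce exactly; `"exact"` uses
the exact quantile 1.959964. Cohen's κ = (pₒ−pₑ)/(1−pₑ) with the
two-sided asymptotic null test (Fleiss large-sample SE); a table with
pₑ = 1 raises rather than returning NaN.

The quality gate precedes diagnosis: roll is the interocular angle
(threshold 5°), yaw is proxied by the ratio of left/right
lateral-canthus-to-iris-midpoint horizontal extents (accepted range
[0.8, 1.25]). The CLI refuses to emit labels for flagged images unless
`--force` is passed.

## Synthetic faces and cohorts

The renderer draws schematic frontal faces — skin ellipse, almond
eyelid contours (16-point polygons with separate upper/lower
amplitudes), iris disks clipped by the palpebral opening, brow bands —
and emits the exact construction coordinates as landmarks, so
`measure_distances` on an emitted set reproduces the generating
parameters to 1e-9. Pathology is parametric: per-eye iris offsets
(strabismus), upper-lid droop (ptosis), roll (rotation of everything
about the face center), and yaw realised as a cylindrical
weak-perspective projection solved so that the rendered extent ratio
equals the requested value. All randomness (skin noise) flows from the
single seed. Neutral geometry: interocular 120 px on a 320 px canvas,
palpebral half-width 30 px, apertures 15/12 px, iris radius 9 px —
chosen so the default distance means (30 px canthal, 15 px MRD1) match
the cohort simulator.

The cohort simulator draws measure tables directly from per-measure
distributions — default Normal with SD 3.3 px, the scale of healthy
periocular pixel-distance variability at ~1024 px face resolution, with
means matching the renderer geometry; lognormal families are available
for non-normal scenarios. Abnormalities are injected with a default
15 px effect size, chosen to be physically consistent: vertical offsets
much larger than the lid aperture would place the iris beyond the lid
and fold the absolute distance measure back toward normal.

What the synthetic data does *not* emulate: photographic texture,
specular highlights, occlusions (glasses, hair), detector landmark
noise, and correlated anatomy (measures are drawn independently, so
real-cohort covariance between, say, canthal width and brow height is
absent). Passing tests therefore validate the geometry, the statistics
and the pipeline contracts — not detector robustness on real
photographs, which enters through the `LandmarkDetector` plug-in and
must be validated separately.

## Numerical choices and degenerate inputs

- Bilinear resampling everywhere; white fill for out-of-frame pixels.
- Gaussian kernels truncated at 3σ with reflect padding.
- Final composites and color transfers round half-to-even before the
  uint8 cast; identical inputs give byte-identical PNGs.
- Affine fits raise on collinear/coincident configurations; the
  similarity solver excludes reflections.
- `iris_center` of coincident eyes, zero-weight masks, non-positive σ,
  sub-4-sample IQR input, benchmark measures with fewer than 8
  post-filter samples, and κ on degenerate tables all raise structured
  errors naming the offending quantity.
- Bootstrap intervals require an explicit seed; there is no hidden
  global random state anywhere in the package.

## Experiment sizes

The verification experiments use: 48 patient/avatar fusion pairs with
injected offsets δ ∈ {4, 8, 12} px at avatar scales 1.0 and 1.2
(tolerance 0.5 px); cohorts of n = 200 for benchmark fitting; 500
seeded replicates for bootstrap ci_mean coverage (expected 95% ± 3%);
300 injected-abnormality subjects and 400 clean eyes for
sensitivity/false-positive measurement. These sizes give ±2–3%
Monte-Carlo precision on the rates they estimate while keeping a full
run around ten seconds.

## Known limitations

- All geometry is planar; 3D landmark depth, out-of-plane pose beyond
  the quality-gate proxies, and perspective are not modelled.
- The color-harmonization model is global per channel over the skin
  ring; strong illumination gradients across an eye are not corrected.
- The benchmark assumes a fixed face scale (pixel units). Comparing
  across capture setups requires the fusion scale factor or an external
  ruler; no automatic metric calibration is attempted.
- Avatar selection (age/sex matching) and avatar synthesis are out of
  scope; avatars are plain image inputs.
- The classifier is a screening rule on 2D distances, not a clinical
  diagnosis; borderline bilateral presentations (both eyes deviating
  symmetrically) reduce the asymmetry signal by construction.
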