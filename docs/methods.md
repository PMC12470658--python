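# Methods

## Geometry and the thickness map

A macular cube is a raster of `n_slow` B-scans × `n_fast` A-scans
(defaults 128 × 512) over a 6 × 6 mm en-face area, giving anisotropic
sampling of 11.72 µm (fast) × 46.88 µm (slow).  All zone geometry works
in physical millimetres on cell centers, so the anisotropy is handled
uniformly; the fast axis is x, and nasal is +x for a right eye (OS is
mirrored).  The axial scale defaults to 1.95 µm/px (≈ 2 mm depth over
1024 pixels, typical of the device class); it is configurable because
vendors do not publish it consistently.

The EZ-RPE thickness at an A-scan is `RPE depth − EZ depth`, clamped at
zero: after manual correction, boundaries may touch (a collapsed
outer-segment compartment) but a negative gap is a segmentation artifact.
Crossings beyond a 2 µm tolerance invalidate the A-scan instead.  Invalid
A-scans carry no measurement and are excluded from every numerator *and*
denominator — attenuation percentages are fractions of *valid* points
(65,536 when the cube is complete).

## Metrics

* **Partial attenuation** = 100 × #{valid points with thickness ≤ 20 µm} /
  #valid.  The threshold comparison is inclusive, following the standard
  "≤ 20 µm" definition.  **Total attenuation** uses threshold 0, which
  after clamping is an exact-zero test.
* **Zones** are full discs centered on the fovea: central subfield
  r = 0.5 mm, parafoveal r = 1.0 mm.  The parafoveal zone is deliberately
  a *disc*, not a 0.5–1.0 mm annulus: with the cohort-mean thicknesses
  (40.4 µm central, 36.8 µm parafoveal) the disc convention reproduces
  the reported zone volumes (0.032 and 0.12 mm³) at print precision,
  while an annular volume does not.  A disc-mean and an annulus-mean of
  thickness are not distinguishable at the reported precision; the disc
  was adopted for consistency with the volumes.
* **Zone volume** = Σ thickness(mm) × cell area(mm²) over valid in-zone
  points.  On a uniform field this converges to `T·πr²` as the grid is
  refined (verified at 4× oversampling within 2 %).
* **Point thicknesses** sample the horizontal meridian through the fovea
  at ±0.5 / ±1.0 mm by bilinear interpolation of the four surrounding
  cell centers, renormalizing weights over valid neighbors; a location
  with no valid neighbor is an error, as is one outside the cube.
* The foveal center defaults to the cube center ("centered on the
  fovea"); a configurable offset supports decentration experiments, but
  there is no automatic fovea detection.

Report tables print percentages and thicknesses at 1 dp, the central
subfield volume at 3 dp and other volumes at 2 dp, matching the precision
conventions of the screening literature.

## Progression rule

An eye is flagged when its **partial** attenuation increases by
≥ 4.0 percentage points (absolute) between the two OCTs.  Two choices
here were genuinely open and are exposed as flags:

* *Which metric*: the screening literature operationalizes the rule on
  partial attenuation (mild-toxicity eyes differ from normative eyes by
  ≈ 4 % in partial attenuation) even where "total" appears in prose;
  `metric="total_attenuation_pct"` switches it.
* *Inclusivity*: "≥ 4 %" and "more than 4 %" both appear in common
  descriptions; the inclusive reading is the default
  (`inclusive=False` switches it).

## Synthetic data

The generator exists so every downstream stage is testable without
patient data; it emulates the *statistical structure* the analysis
assumes, not OCT physics.

**Thickness phenotype.**  T(r) = base(r) − depth·exp(−(r−c)²/2σ²) +
ε, clamped ≥ 0, with base(r) interpolating the central-subfield mean
(40.4 µm) to the parafoveal mean (36.8 µm) over the first millimetre and
declining at 1 µm/mm beyond it.  The annular Gaussian dip (center
c = 1.2 mm, width σ = 0.4 mm) stylizes early parafoveal thinning; no
published spatial model exists, so the annulus is one plausible, fully
configurable choice.  Progressors deepen the dip from 10 µm at OCT1 to
35 µm at OCT2 (crossing the ≤ 20 µm threshold over an annulus of a few
mm²); stable eyes have no dip and differ between timepoints only by the
per-point measurement noise ε ~ N(0, 1.5 µm).  The helper
`ring_depth_for_attenuation` inverts the continuum annulus area for the
dip depth that yields a target attenuated fraction (bracketing +
Brent root-finding on a 4000-point radial grid; it requires the region to
stay inside the inscribed circle of the scan).

**Intensity cubes.**  Per A-scan, four Gaussian bright bands (σ = 5 µm;
amplitudes ILM 0.9, OPL 0.55, EZ 0.85, RPE 1.0) over a 0.05 background,
with a flat RPE at 350 µm depth, a stylized foveal pit and ONL bulge, and
multiplicative log-normal speckle (σ = 0.35 by default, mean-one).  This
is enough to exercise band detection, the merged-band regime, and noise
robustness.  Deliberately *not* modeled: attenuation/shadowing, motion
artifacts, tilt, vessel shadows, real speckle statistics, pathology other
than outer-retinal thinning.  Passing tests therefore certify the
pipeline's arithmetic and its behavior under band merging and speckle —
not segmentation performance on device images.

**Cohorts.**  373 eyes, 34 progressors by default.  Covariates are
sampled independently within group (no covariance structure is
published): age at HCQ initiation N(61.6, 13.0) for progressors vs
N(50.5, 12.1) for stable eyes; baseline logMAR N(0.20, 0.24) vs
N(0.08, 0.16) floored at −0.12; OCT interval N(3.1, 0.9) truncated at
1 year; duration, doses and demographics at cohort-level rates.
Clinician/expert toxicity labels are assigned by explicit count targets
(scaled from the default concordance counts) rather than a behavioral
model — only the counts are known.  `fixture_cohort_from_counts` builds a
fully deterministic cohort whose flag/label contingency equals a given
set of integer counts exactly, for arithmetic verification.

## Segmentation

Per A-scan: Gaussian template correlation along depth, peak detection
(prominence ≥ 0.12, minimum separation 4 px), assignment of up to four
peaks to ILM/OPL/EZ/RPE by depth order, parabolic sub-pixel refinement.
Numerical choices that matter:

* The correlation template is 0.7× the band width: full-width smoothing
  pulls the nearly-merged EZ and RPE peaks toward each other and biases
  thin gaps low.
* **Three resolvable bands** are interpreted as a merged EZ+RPE complex
  (EZ = RPE, thickness 0).  In attenuated retina the two bands collapse;
  marking those A-scans invalid would remove exactly the attenuated
  points from the denominator and bias the attenuation percentage.
* The running-median continuity constraint (window 7, tolerance 6 px)
  applies to the ILM, OPL and RPE only.  The EZ is exempt: at an
  attenuation edge it legitimately jumps onto the RPE.
* Cube-level segmentation median-filters each surface across 3 frames and
  re-validates, so the output always satisfies the non-crossing invariant
  or masks the violation.

The fidelity target is end-to-end metric error (≤ 1 pp attenuation,
≤ 2 µm zone thickness at default noise), not equivalence to any
particular clinical platform, whose algorithm is unpublished.

## Statistics

Longitudinal change uses two-sided paired t-tests per metric;
flagged-vs-unflagged comparisons use Welch's two-sample t (the groups are
independent and unequal, 34 vs 339, so a paired test is not applicable);
categorical covariates use chi-square, falling back to Fisher's exact for
2×2 tables with any expected cell ≤ 5 (Cochran's rule, applied
inclusively so the boundary case goes to the exact test).  Zero-variance
inputs are guarded explicitly: p = 1 for no change, p = 0 for a constant
nonzero shift.  All tests are two-sided at α = 0.05 with no
multiple-testing correction (analyses are univariable by design).
Cohen's kappa is computed from the agreement table; the degenerate
both-raters-constant case returns 1 for perfect agreement and 0
otherwise.  logMAR→Snellen conversion snaps 20×10^logMAR to the nearest
standard chart line in log space.

## Problem sizes

Exhaustive-loop oracle checks run on grids up to 20×20; truth-field
attenuation recovery runs at the full 512 × 128 grid; the end-to-end
intensity→segmentation→metrics check uses 20 eyes at 128 × 64 × 320
voxels; the 100-seed cohort sign-recovery check simulates 373-eye cohorts
on a 64 × 64 en-face grid (attenuation percentages are area fractions and
grid-resolution-independent to well below the tolerances).  These sizes
are the package's own defaults for its verification suite and keep the
whole suite under a minute on one core.

## Known limitations

* The phenotype is radially symmetric; real HCQ damage is often
  asymmetric (nasal-predominant thinning is reported).
* Labels are count-matched, not behaviorally modeled, so concordance
  checks verify arithmetic, not reader behavior.
* The segmenter is a desk-scale stand-in: template correlation + order
  assignment, with no robustness to device artifacts and no learning
  component.
* One eye per subject, two timepoints, no mixed models or survival
  analysis — matching the univariable design it reproduces.
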