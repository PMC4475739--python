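# Methods

This note documents the models, algorithms, parameter defaults and design
choices behind retmorph, and what the synthetic-data validation does and
does not establish about real fundus photographs.

## Coordinate and unit conventions

All rasters are 8-bit; coordinates are 0-based `(row, col)` with row
increasing downward. Every geometric output is in pixel units. Fundus
cameras rarely export a trustworthy physical scale and none is assumed; a
`pixel_size` field exists on `FundusImage` for callers who have a
calibration, but no module converts units. The "red-free" working image is
the green channel of RGB input — the standard ophthalmic convention, since
hemoglobin absorbs strongly in green and vessels show maximal contrast
there.

## Vessel extraction

Retinal vessels are dark, elongated, and ride on a bright, unevenly
illuminated background. The chain is:

1. **Lesion (confounder) removal** — pixels deviating from the local median
   (window half-width 4 px) by more than 30 gray levels, in either
   direction, are candidate lesions (bright exudate/microaneurysm
   analogues, dark hemorrhages). A thin vessel also deviates from the
   window median wherever it fills less than half the window, so candidate
   components are required to be *compact*: after closing with a
   window-sized disk, any component larger than 16 px in either bounding
   direction is treated as vasculature and left untouched. Surviving lesion
   pixels are in-painted with the local median. The window must be smaller
   than the thinnest vessel of interest yet larger than the lesions to be
   removed; the defaults remove blobs up to ~8 px across while preserving
   3-px branches. Lesion removal runs before background subtraction
   (focal blobs otherwise distort the background estimate); the order is
   configurable.
2. **Background flattening** — iterative rolling-ball subtraction (radius
   25 px, 2 iterations by default). The image is inverted internally so the
   dark vessels are the bright features the rolling ball preserves; the
   output is the residual with vessels bright on a near-zero background,
   and a constant image maps to all zeros. The ball radius must exceed the
   largest vessel half-width (25 px covers calibers up to ~50 px).
3. **Binarization and skeletonization** — Otsu threshold on the residual
   (a fixed threshold is available), removal of speckle components below
   20 px, then topology-preserving 8-connected thinning. The skeleton is
   guaranteed one pixel wide (no 2×2 foreground block) and a subset of the
   vessel mask.

## Tracking

The skeleton is an 8-connected pixel graph with Euclidean step costs (1
axial, √2 diagonal). Operator endpoints are snapped to the nearest skeleton
pixel (ties: smaller row, then column; failure beyond 10 px raises an
error). A* with the straight-line admissible heuristic returns a provably
shortest centerline path; frontier ties break on (smaller heuristic, then
row-major order), making tracking fully deterministic. Search never leaves
the skeleton, so the path follows the vessel even when a chord would be
shorter.

## Caliber and AVR

Width at a centerline pixel is `2·EDT − 1`, where EDT is the distance to
the nearest background pixel: the nearest background *pixel center* lies
half a pixel beyond the true edge on each side, so the subtraction makes
the estimate exact for straight vessels of odd drawn width and unbiased to
within ~half a pixel elsewhere. (Perpendicular ray-casting with subpixel
edge interpolation is available as `method="ray"`; it agrees with the
distance-transform estimate to within a pixel on straight vessels and is
slower.) Widths below 1 px are clamped to 1 (a skeleton-only degenerate
vessel is one pixel wide by construction). Segment width is the unweighted
mean over all path pixels; no endpoint trimming is applied. AVR is the
ratio of the two class means of the 2 + 2 selected segments and is
dimensionless, hence independent of any global scale.

## Tortuosity

The path is rotated/translated so its chord lies on the x-axis with both
endpoints at y = 0. If the aligned path is single-valued in x (fewer than
20% of steps non-increasing; minor pixel jitter is absorbed by keeping the
strictly increasing subsequence), a cubic smoothing spline g is fitted and
the residual linear ramp between g(0) and g(L) is subtracted, enforcing
f(0) = f(L) = 0 exactly. Hairpin vessels that double back past vertical
fall back to arc-length parameterization (x := cumulative arc length,
y := signed perpendicular deviation from the chord) and the result is
flagged.

* Spline residual budget: `s = smoothing · n` with `smoothing = 0.25` by
  default — about half a pixel of allowed RMS deviation per point, matched
  to the quantization noise of integer skeleton paths. For analytic,
  noise-free point sets pass `smoothing = 0` (interpolation).
* **Directional changes**: f′ is sampled every 0.1 px; each sign flip is
  refined by bracketed root finding; a flat zero-run counts once only if
  the sign differs across it (a straight vessel has none); roots within
  2 px of each other are merged and roots within 2 px of an endpoint are
  discarded (spline edge effects).
* **Area**: ∫|f| dx, split at the zeros of f so each piece is smooth for
  adaptive quadrature. The absolute value is deliberate — vessels cross
  their chord, and signed area would cancel.
* **Indices**: `ti_composite = K_dc·N_dc/L + K_area·area/L²` with chord
  length L; `ti_integral = area/L`; `ti_arc_chord = (polyline arc
  length)/L`. Chord length (not curve length) is the normalizer: the chord
  frame fixes the natural x-extent, and using curve length would let a
  tortuous vessel partially normalize away its own tortuosity (a flag for
  curve-length normalization is deliberately not offered; change the
  constants instead). The default weights K_dc = 1000, K_area = 100 put
  the composite on a convenient 0–100 scale for segment chords of a few
  hundred pixels and weight the change-count term dominantly; they are
  config-exposed, and only *relative* comparisons under a fixed
  configuration are meaningful — the absolute scale of any composite
  tortuosity index is a convention.

On sinusoids of amplitude A and k periods over chord L the implementation
reproduces the closed forms: N_dc = 2k exactly for k = 1..5, area =
2AL/π ± 1% independent of k, arc/chord of a semicircle = π/2 ± 1%. The
frequency-invariance of the area is the quantitative argument for the
composite index: only the change-count term distinguishes slow bowing from
rapid undulation.

## Optic disc, ROI and fractal dimension

The local-variance filter (15-px window) lights up structure boundaries.
Vessels become solid high-variance stripes; the disc — bright and
internally uniform — becomes a high-variance *ring* around a low-variance
interior. After Otsu thresholding of the local standard deviation, the disc
is found as the most circular enclosed hole of the mask (circularity
4πA/P², candidates restricted to 0.2–8% of the image area). Using holes
rather than filled components is what makes the detector robust to the
vessel tree, whose junction clusters can otherwise form large, deceptively
round blobs. The reported radius adds half the variance window to the
hole's equivalent-circle radius, compensating the inward spread of the
rim's edge response. Detection fails explicitly (circularity < 0.6 or no
candidate) and the pipeline then honors a manually placed ROI — discs
clipped by the image border or obscured by papilledema need this fallback.

The analysis ROI is the circle of 3.5× the disc diameter concentric with
the disc, clipped at image borders (clipping fraction reported). The disc
interior is excluded from the fractal ROI by default: after outlining it
contains no vascular signal, and its rim would contribute spurious
structure. Within the ROI the vasculature is background-subtracted,
Otsu-binarized, despeckled (3×3 binary median) and reduced to 1-px
outlines (mask minus its erosion); box counting runs on the outline image.

Box sizes form the geometric series {2, 4, 8, ...} capped at **1/8 of the
foreground bounding-box extent**: counts in boxes comparable to the pattern
itself are dominated by grid alignment, and with a larger cap the estimate
drifts by ~0.1 under mere translation of the pattern, versus ~0.00 with
this cap. Grid origin 0 is (0,0); three further pseudo-random origins
(default seed 17) are averaged into mean-D, with per-origin log–log r²
reported and a quality warning below 0.95. On 512² rasters the estimator
gives 0.98 for a line, 1.95 for a filled square, and 1.59 for a depth-7
Sierpinski gasket (theory 1, 2, log3/log2 ≈ 1.585).

## Statistics

* **Group comparison**: Wilcoxon signed-rank on matched pairs, zero
  differences dropped, exact distribution up to 25 non-zero pairs and
  normal approximation with continuity correction above (scipy's
  implementation stands behind this surface; the test suite checks it
  against full sign-pattern enumeration).
* **Cutoffs**: exact 1-D 2-means. For one-dimensional data the optimal
  2-means partition is a split of the sorted values, so the implementation
  scans all n−1 split points for minimum within-cluster sum of squares and
  returns the midpoint of the two cluster means — deterministic, order
  invariant, and globally optimal where Lloyd iteration can stall.
  Abnormality directions are fixed: AVR below, TI above, mean-D below the
  cutoff. Reference clinical cutoffs (0.70 / 72 / 1.42) ship as
  `REFERENCE_CUTOFFS` for fixed-cutoff classification.
* **Classification**: disease is the positive class. The combined
  three-index rule defaults to the AVR decision — adding TI and mean-D to
  the clustering does not change the assignment, so the combined row equals
  the AVR row; an OR-rule alternative is config-exposed. Metrics are
  percentages; an empty denominator yields "not available" (None), never 0.
* **Intervals**: exact Clopper–Pearson for sensitivity, specificity, PPV,
  NPV (for 11/16 this gives 41.3–89.0%, matching the conventionally quoted
  41.4–88.9 to within rounding of the beta quantiles).
* **Reliability**: ICC(2,1) — two-way random effects, absolute agreement,
  single measures (pingouin's estimator), reported as a percentage;
  undefined (zero between-subject variance) reported as None.

## Synthetic data: what it emulates and what it does not

`synthetic.generate` renders: a background with radial illumination falloff
and low-frequency Gaussian texture (so rolling-ball subtraction is
exercised non-trivially); a bright disc (radius 40 px, +45 gray levels,
soft 1.5-px rim) at mid-left; four annotated vessels (sinusoidal
centerlines, default widths 7 px arteriole / 11 px venule) leaving the disc
radially; a recursive binary branching tree (level-0 chord 50 px, length
×0.7 and width ×0.78 per level, ±26° spread) sized so all levels fall
inside the 3.5× ROI; and optional bright/dark lesion disks. Vessels are
drawn with an anti-aliased edge whose 50% level sits exactly at the drawn
half-width, so thresholding recovers odd integer widths exactly — odd
widths have a well-defined single-pixel midline and are therefore the
generator's default. Everything is deterministic per seed.

`generate_cohort` simulates matched pairs at the *index* level with a
variance-components model: control means (0.77, 64, 1.45) for (AVR, TI,
mean-D); between-pair SDs (0.067, 23.5, 0.031); within-pair residual SDs
(0.03, 3.5, 0.015); independent per-rater noise with the same SDs; disease
shifts (−0.09, +8, −0.04) by default. The components sum to cross-sectional
spreads of ~0.08 / 24 / 0.04 — the spread observed in matched cohorts —
while the small within-pair residuals encode the premise of a matched
design: pairing on age and gender removes most between-subject variation.
Under these conditions all three indices are detected (paired Wilcoxon,
p < 0.05, n = 16 pairs) in ≥ 97% of replicates, and zero-effect nulls give
uniform p. `subject_image_spec` maps index values onto renderable image
parameters (narrower arterioles ↔ lower AVR, more sinusoid periods ↔
higher TI, shallower branching ↔ lower mean-D) for image-level integration
runs; simulating a full cohort through the image pipeline is supported but
not the default, as the index-level model is what the statistical claims
depend on.

Passing on synthetic data shows that each stage recovers its own ground
truth and that the chain composes; it does not certify performance on real
photographs, whose pathology spectrum, camera optics, central vessel
reflex, and segmentation failure modes the generator deliberately does not
model (no photorealism, no illumination effects beyond a radial gradient).

## Pipeline behavior and reproducibility

`analyze_image` runs extraction once, then per-segment tracking → caliber →
tortuosity, AVR over the 2+2 profiles, and the disc/ROI/fractal chain.
Stage failures are caught and recorded with the stage name; later stages
still run, so a short annotation file yields a partial report with explicit
error entries rather than nothing. Warnings (clipped ROI, low r², curve
fallback, empty masks) are surfaced in the report. Every report embeds the
effective configuration; identical input, configuration and seed reproduce
reports bit-for-bit. The problem sizes used throughout the validation suite
(480² images, 512² fractal rasters, 20 synthetic trees, 200 cohort
replicates at 16 pairs) were chosen as the smallest at which each check is
statistically meaningful.

## Known limitations

* Vessel class comes from the operator annotation; there is no automatic
  artery/vein discrimination.
* The caliber estimator assumes the mask locally brackets the true vessel;
  central light reflex (bright vessel core) is not modeled or corrected.
* Chord-frame tortuosity requires a dominant direction; hairpins use the
  arc-length fallback, whose area term is not strictly comparable to the
  chord-frame one (the flag travels with the result).
* Disc detection expects a closed rim inside the image; discs cut by the
  frame need the manual ROI path.
* Absolute TI and mean-D values depend on configuration (weights, box-size
  series, outlining); only comparisons under a fixed configuration are
  meaningful.
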