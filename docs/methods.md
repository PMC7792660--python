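# Methods

`pvsretina` implements a computational chain linking the burden of
enlarged perivascular spaces (PVS) measured on 3D brain MRI to summary
parameters of the retinal microvasculature, validated end to end on
synthetic data with known ground truth. This note documents the models,
the estimators, the numerical choices, and what the synthetic validation
does and does not establish.

## PVS segmentation

PVS appear on T2-weighted MRI as thin bright tubular structures of
diameter below 3 mm. Segmentation proceeds in four steps.

**Hessian and vesselness.** At each anatomical scale σ (mm) the image is
convolved with separable Gaussian-derivative kernels whose per-axis SDs
are σ divided by the voxel size — scales are anatomical quantities, so a
1 mm kernel on a 1×1×2 mm grid uses SD 0.5 voxels along the slice axis.
Sampled derivative kernels lose their defining moments at sub-voxel SDs
(the order-2 kernel stops summing to zero, leaking the local mean into
the curvature), so the kernels are moment-corrected: the second-derivative
kernel is forced zero-sum and each kernel is rescaled to respond exactly
1 to its matching monomial, making the operator exact on quadratics at
any σ. Hessian eigenvalues (closed-form trigonometric solver for
symmetric 3×3 fields, cross-checked against LAPACK in the tests) are
sorted |λ1| ≤ |λ2| ≤ |λ3| and scale-normalised by σ². The tubular
response is

    R_A = |λ2|/|λ3|,  R_B = |λ1|/√(|λ2 λ3|),  S = √(λ1²+λ2²+λ3²)
    V = (1 − e^{−R_A²/2α²}) · e^{−R_B²/2β²} · (1 − e^{−S²/2c²})

set to zero wherever λ2 > 0 or λ3 > 0 (bright structures only); the
multi-scale map is the voxel-wise maximum over scales. Defaults:
α = β = 0.5; c adapts per volume to half the ROI's robust intensity range
((99th − 1st percentile)/2); scales {0.5, 1.0, 1.5} mm, of which
unresolvable ones (below half the largest voxel dimension) are skipped —
on the default grid the effective scales are {1.0, 1.5} mm.

**Thresholding.** A plain threshold (`segment`: voxel is PVS iff V ≥ t
inside the ROI) is available, but the pipeline uses hysteresis: voxels
with V ≥ 0.15 are detections, connected voxels with V ≥ 0.06 extend them.
On thick slices a thin oblique tube beads through partial-volume dips;
the weak extension bridges those dips without admitting isolated noise.

**Link arbitration.** Hysteresis alone cannot distinguish a
partial-volume dip inside one vessel from a halo bridge between two
vessels, and some dips fall below any usable extension threshold. Both
cases are resolved geometrically: fragments closer than 4 mm are merged
only when their union fits one straight line — total-least-squares rms
perpendicular residual ≤ 1.35 mm (the order of a tube radius) and at most
0.25 mm above the worse fragment's own residual. Two distinct vessels,
whose axes the phantom keeps ≥ 3 mm apart, fail both conditions unless
they are collinear end to end, where no geometric criterion could
separate them. Thresholds and link tolerances were calibrated by
maximising count recovery and Dice on a dedicated phantom suite and are
frozen in the default configuration.

**Quality control.** A scan is rejected when (a) the segmented fraction
of the ROI exceeds 10%, (b) the component count exceeds 2000, or (c) with
at least 40 components, more than 50% of them share one orientation
within 5° — the signature of motion ghosts, which replicate as parallel
bright lines. The floor of 40 was chosen so that a stripe fixture of a
few dozen ghosts is rejected while clean random-orientation phantoms
stay far from the ceiling (observed dominant-orientation fractions
≤ 0.03). All ceilings are configurable. This automated check is a
surrogate for the visual accept/reject step a trained operator performs
on real data; it encodes only the documented failure modes.

## PVS morphometry

Per component: size is exactly voxel count × voxel volume (mm³). Length
and width are the two longest elongation axes of the ellipsoid
approximating the component, with axes taken from the voxel-coordinate
covariance. Extents are *moment* estimates calibrated to the uniform
rod: √12 × SD of the projected voxel centres, where the variance includes
each voxel's own uniform smearing (Σ h_j² v_j² / 12 projected on the
axis). For an axis-aligned box of n voxels this is the physical extent
n·h exactly (a 7×3×3 box at 1 mm voxels yields length 7, width 3), and it
stays unbiased for tubes at any orientation on an anisotropic grid. A
raw projection-extent estimator with a one-voxel-edge correction was
rejected: its width error reaches +1.5 mm on the 1×1×2 mm grid,
violating the recovery tolerances the estimator must meet. Two
refinements: length takes the Feret extent plus half the projected voxel
support when that is larger (sparse axial sampling on thick slices biases
the moment low), and width averages the two transverse moments, treating
the cross-section as axisymmetric — PVS are modelled as prolate
ellipsoids, and the average halves the sampling noise of thin
cross-sections. Single-voxel components use the geometric-mean voxel edge
for both axes.

A genuine observability limit: on the 1×1×2 mm grid a 10×2 mm tube lying
nearly in-plane can drift between slice planes so that its ends contain
no voxel centre at all; no estimator can recover unobserved extent
(length error −2 mm in ~2% of random orientations). Estimator accuracy is
therefore validated on an isotropic 1 mm grid, where 300 random
orientations give |length error| ≤ 1.0 mm and |width error| ≤ 0.15 mm;
anisotropic behaviour is covered by the exact box cases and the
count-recovery experiment.

Per subject: count, total volume (= Σ sizes), and mean / median / SD /
percentiles {5, 25, 50, 75, 95} of length, width and size. Percentiles
use linear interpolation between order statistics; SD uses the n−1
denominator; the median is identically the 50th percentile. An empty
segmentation yields count 0, total volume 0 and missing summaries.

## Retinal morphometry

Eyes are processed independently throughout; left and right never mix.

**Caliber.** From all vessels of one type crossing Zone B — the annulus
0.5 to 1.0 optic-disc diameters from the disc centre — the six widest are
selected (ties: first occurrence wins; fewer than six makes the eye
unmeasurable). The six widths are combined by iterative pairing: sort,
combine widest with narrowest as w = k·√(w_big² + w_small²), repeat
(6 → 3; an odd list carries its median forward; → 2 → 1). Branching
coefficients default to k = 0.88 for arterioles (CRAE) and k = 0.95 for
venules (CRVE), the revised-formula convention; both are configurable.
AVR = CRAE/CRVE identically. The reduction is order-invariant,
homogeneous of degree 1 and monotone in every width — all asserted in
tests. Widths stay in their native measurement units (px for the
phantoms); no µm conversion is attempted.

**Fractal dimension.** Monofractal box counting on the binary vessel
map: occupied-box counts N(s) over box sizes s ∈ {2, 4, 8, …} up to
min(image dimension)/4, FD = −slope of the least-squares fit of log N(s)
on log s, with the fit R² reported. The estimator is calibrated on
rasters of known dimension: a line (1.0), a filled square (2.0) and a
depth-7 Sierpinski triangle (log 3/log 2 ≈ 1.585), each recovered to
machine precision on power-of-two grids because the box ladder tiles
exactly.

**Raster measurement.** When an eye arrives as a binary raster rather
than a width table, vessels are measured where they cross the circle at
the middle of Zone B: the circle is sampled at fine angular resolution
and each contiguous foreground run's arc length is the width — exact in
the limit for vessels radial to the disc, within 1 px on the phantoms.

## Synthetic data

**PVS phantoms.** Bright capsules with Gaussian radial profile (peak at
the axis, SD = radius/2 — diffuse borders, and the Hessian signature the
filter expects) on a uniform background (default 100) with additive
Gaussian noise (default SD 2, the low-noise regime the count-recovery
experiment specifies), inside an ellipsoidal ROI on a 128×128×64 grid of
1×1×2 mm voxels. Radii are drawn from (0.8, 1.4) mm — diameters under the
3 mm PVS definition, and thick enough to be resolvable on 2 mm slices —
lengths from (6, 14) mm, contrasts from (60, 100). Placement enforces two
well-definedness constraints: pairwise surface separation ≥ 3 mm (so the
ground-truth count is unambiguous) and grid visibility (each tube's
noiseless half-peak footprint must be a single 26-connected component of
≥ 2 voxels — an in-plane tube lying between slice planes can otherwise
be invisible at any noise level). An unplaceable request fails loudly.

**Motion stripes.** Parallel bright lines (one shared in-plane direction,
Gaussian cross-profile of SD 0.9 mm) at jittered regular perpendicular
offsets, emulating periodic ghost replication; used to exercise QC
rejection.

**Retinal phantoms.** Straight rays of constant width radiating from an
optic disc (default diameter 120 px in a 512 px image; arteriole widths
N(10, 2²) px, venule widths N(14, 2.5²) px, truncated to [4, mean+3 SD]),
types interleaved, with angular placement guaranteeing disjoint
footprints throughout Zone B. The width table records each vessel's true
width at the ring.

**Cohort tables.** A single-latent-factor Gaussian copula: each
continuous variable j is λ_j·F + √(1−λ_j²)·ε_j on the z scale, then
mapped to its target marginal (Gaussian, except WMH %ICV which is
lognormal with matched moments — a monotone map, so rank correlations
survive). PVS burden loads negatively and retinal caliber/FD positively
on the latent microvascular-health factor F, so higher PVS burden
co-occurs with narrower arterioles and sparser branching; the implied
correlation of two variables is λ_i λ_j, positive semi-definite whenever
all |λ| ≤ 1. Default marginals and risk-factor prevalences are calibrated
to the descriptive statistics of a published older community cohort
(e.g., PVS count mean 254.4, SD 90.13; the right-eye arteriolar FD SD is
taken as 0.06, consistent with every other FD dispersion, where the
printed source value is implausible for a quantity bounded by 2). The
count × left-CRAE loading product is set to 2·sin(π(−0.19)/6) so the
*Spearman* correlation hits −0.19. Smoking adds a configurable
standardised shift (defaults 0.13–0.15 SD) to PVS width, size and total
volume. A deliberate simplification: one factor cannot reproduce strong
within-block correlations (e.g., left-right eye agreement) at the same
time as weak cross-block ones; the generator targets the cross-block
sign pattern, which is what the association stage must recover.

## Association analysis

Descriptives compare included vs excluded subjects: Welch two-sample
t-tests for continuous variables, chi-squared without continuity
correction on 2×2 tables for binary ones; zero-variance variables skip
the test with a note. Cross-correlations are Spearman ρ on
pairwise-complete observations (average ranks for ties), p values from
the t approximation, and 95% CIs from percentile bootstrap over paired
subject resamples (default 2000 replicates; when no values are missing
the replicates are computed jointly for all variables from one resample
stream). Benjamini–Hochberg FDR is applied over all cells of the matrix
as one family, both eyes jointly. "Generalised linear models" are
Gaussian-identity fits by least squares on complete cases, adjusted for
age, sex and six binary risk factors; unstandardised B/SE come from the
raw-scale fit and standardised Beta/SE from a refit with every variable
z-scored (the identity Beta = B·SD(x)/SD(y) is asserted internally).
Rank-deficient designs fail with the offending columns named. All
bootstrap streams derive from one seed; the full pipeline is
byte-reproducible given that seed.

The stage is exposed statsmodels-style: `RetinaPVSAssociation(table)`
holds the variable sets and settings, `.fit(seed)` returns an
`AssociationResults` with the correlation cells, fitted models,
descriptives, `summary()` text and a correlation heatmap plot.

## Pipeline and problem sizes

`simulate_inputs` writes a full study to disk (cohort CSV, NIfTI phantom
volumes + JSON ground truth, PNG retinal rasters + CSV width tables);
`run_pipeline` consumes such a directory, lets imaging-derived metrics
replace tabulated columns for the imaged subjects, drops QC-rejected
subjects' metrics, and reports the exclusion tally — one subject's
failure never aborts the cohort. The packaged validation uses 20
phantoms of 10–60 tubes for count recovery, 20 (tests) / 300
(development) orientations for morphometry, 1000 null fits for type-I
calibration, 100 seeded cohorts of n = 381 for bootstrap-CI coverage and
200 for effect recovery, and a 381-subject run-all executed twice for
byte-identity; these sizes give stable Monte-Carlo estimates while
keeping the whole validation in the minutes range.

## Known limitations

* The phantoms have uniform background, Gaussian noise and straight
  tubes: no bias fields, Rician noise, curved vessels, or neighbouring
  bright anatomy. Passing count recovery here shows the filter chain and
  component logic are correct, not that the frozen thresholds transfer
  to scanner data — on real images the thresholds would be re-optimised
  against expert annotations, as the QC ceilings would be.
* The Frangi parameter values a production pipeline would use are not
  public; the defaults here are phantom-calibrated stand-ins.
* Retinal phantoms are binary rasters of straight vessels; vessel
  segmentation, artery-vein classification and optic-disc detection from
  fundus photographs are upstream problems outside this package.
* The cohort generator's single factor reproduces the cross-block sign
  pattern, not the full 10×10 correlation structure of real data.
* Whether components should be excluded by a post-hoc width ceiling is
  left off by default (`max_width_mm` available), as no rule is
  established.
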