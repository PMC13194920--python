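# Methods

## The measurement model

`rodmorph` estimates single-cell dimensions of rod-shaped bacteria from 2D
instance-segmentation masks. A cell is modeled as a **spherocylinder**: a
cylinder of diameter w capped by two hemispheres, imaged at its medial
focal plane so that the mask is the cell's axial silhouette. The model
assumes rotational symmetry about the centerline; it tolerates curved rods
(the centerline may bend) but not branched or tapered cells.

Per cell, the pipeline is:

1. **Distance transform.** The exact Euclidean distance from every instance
   pixel to the nearest non-instance pixel. Along the centerline this value
   is the local cell radius in pixels. Raw distances are used, with no
   half-pixel boundary adjustment; the resulting sub-pixel offset is part
   of what the correction model (below) absorbs on real segmentations.
2. **Skeletonization.** Morphological thinning produces a one-pixel-wide,
   8-connected centerline. Thinning is preferred over the topological
   medial axis, which over-branches on noisy rod outlines and thereby
   distorts path-based size estimates.
3. **Skeleton graph.** Each skeleton pixel is a node; nodes closer than
   1.5 px are joined (this admits exactly the 8-neighborhood: steps of 1
   and √2). Degree-1 nodes are endpoints.
4. **Candidate paths.** An unbranched skeleton (two endpoints) yields one
   path covering the whole skeleton. A branched skeleton yields one simple
   path per unordered endpoint pair, found by depth-first search. Cycles
   (possible on noisy masks) are broken with a depth-first spanning tree
   and logged. If a skeleton has more than 12 endpoints, enumeration is
   limited to the 12 most graph-eccentric endpoints and a warning logged.
5. **Slab formulas.** For an ordered path with radii r_ci at its n points,
   cap radii r_s1, r_s2 at its two ends, slab height h = 1 px, and
   successive Euclidean steps d(i, i+1):

       L  = r_s1 + r_s2 + Σ d(i, i+1)
       w̄  = (2/n) Σ r_ci
       S  = 2π (r_s1² + r_s2² + h Σ r_ci)
       V  = π ((2/3) r_s1³ + (2/3) r_s2³ + h Σ r_ci²)

   Lengths scale by the pixel size (µm/px), areas by its square, volumes by
   its cube. The width profile w_i = 2 r_ci is reported alongside.
6. **Branched cells.** Every candidate path is measured and the per-metric
   median reported (median of an even count = mean of the two middle
   values); the cell is flagged `branched`.
7. **Degenerate cells.** Skeletons of ≤ 2 pixels carry no path geometry:
   the cell is flagged `degenerate`, width is reported as twice the maximum
   local radius, and length/surface/volume are absent (NaN). Instances
   split into several connected components are measured on the largest
   component, with the component count recorded.

### Centerline regularization

The slab formulas assume points spaced one pixel apart *along the
centerline*. Raw thinning skeletons violate this in two ways: the
8-connected chain zigzags between axial and diagonal steps, inflating
Σ d(i, i+1) by up to ~8% depending on cell orientation, and its points are
spaced 1 px along the chain rather than along the axis, so diagonally
oriented cells under-tile the cylinder in the S and V sums by up to ~30%.
`measure_cell` therefore smooths each candidate path (Gaussian on the
coordinates, σ = 2 px, endpoints pinned) and resamples it at exactly 1 px
arc-length spacing before applying the formulas. Radii at resampled points
are interpolated **1D along the path** from the per-pixel distance values —
2D interpolation of the distance field would systematically undershoot,
because the field is a ridge peaked on the centerline. With this
regularization the estimator is orientation-independent up to rasterization
noise (verified by the rotation-robustness tests).

### Cap placement

Thinning stops at a mask-dependent point: sometimes short of the
hemispherical cap (the end radius then measures the lateral wall and the
tip is lost from the length sum), sometimes deep inside it (the unit slabs
then under-tile the cell body). Both are repaired geometrically before
measurement: ends whose radius has dropped more than ~0.5 px below the
local maximum radius are trimmed back, then each end is extended along its
outward tangent toward the mask tip — located as the instance pixel
farthest along that direction — until the remaining tip distance is
accounted for by the end radius. On an ideal spherocylinder both rules
place the endpoint about half a slab into the cap, where the
distance-transform value equals the distance to the tip; this makes the
length formula exact and the slab quadrature of S and V unbiased. The
half-slab target is the point at which unit slabs exactly tile the
cylindrical body, leaving the hemisphere term to cover the rest; it is a
quadrature-matching argument, not a fitted constant.

### Accuracy on ideal masks

On ideal digital spherocylinders at 65 nm/px (widths 0.53–1.04 µm, lengths
2–8 µm, random orientations) the estimator recovers width within ±1.5 px
and tip-to-tip length within ±2 px per cell, and surface/volume without
systematic bias (ensemble mean error well under 5%). Per-cell S and V
deviations of up to ~±15% remain for the thinnest cells at axis-aligned
orientations: a digital rod 8 px across determines its own true width only
to within about one pixel (masks rasterized from widths differing by less
than the rasterization phase are identical), and this irreducible ±0.5 px
radius ambiguity is ~12% of r² for r ≈ 4 px. No estimator can do better
from the mask alone; on real segmentations the correction model absorbs
the systematic part.

### Shape descriptors and intensity profiles

Cross-sectional area, convex hull area, eccentricity and solidity are read
directly from the binary region via image moments (scikit-image
`regionprops`). Note that the discrete convex-hull convention keeps
digital-disk solidity near 0.93 for small disks; it approaches 1 only as
the region grows. Intensity profiles are sampled by bilinear interpolation
along a line (default 24 samples at 1 px spacing), typically perpendicular
to the cell axis, where the two membrane peaks delimit the cell boundary.

## Bias correction

Automatic segmenters trained on fluorescent-membrane images draw masks
slightly wider than the true outline, inflating every size metric roughly
linearly. Given paired per-cell measurements (automatic, ground truth),
the model

    truth_i ~ Normal(m · auto_i + n, σ),
    m, n ~ Normal(0, 20),   σ ~ Half-Cauchy(10)

is fitted by MCMC. The truth-on-automatic direction is used because the
fitted map is applied to predict the true size of new automatic
measurements. The Half-Cauchy scale (10) is weakly informative for
µm-scale residuals and configurable.

The sampler is the emcee affine-invariant ensemble sampler: each chain is
an independent ensemble run of 8 walkers started near the least-squares
solution, with 300 warm-up steps discarded and the walker draws flattened
and trimmed to exactly `draws_per_chain` retained draws per chain (default
4 chains × 3000 draws = 12000). Split-R̂ is computed per parameter
(arviz) and a warning logged above 1.05 — expected, for instance, when σ
collapses toward zero on noiseless data, where the posterior means remain
accurate but σ chains mix slowly. Seeded runs are bit-reproducible.

To correct a measurement x, K (default 250) (m, n) pairs are drawn jointly
— preserving the slope/intercept posterior correlation — uniformly with
replacement from the pooled draws; the corrected distribution is
{m_k·x + n_k} with its median as the point estimate. No Normal(0, σ)
observation noise is added; σ is retained for diagnostics only. One model
is fitted per size metric (width, length, surface, volume).

Distribution-level comparisons: a histogram Kullback–Leibler divergence
KL(test ‖ reference) on shared bins spanning the pooled range
(Freedman–Diaconis bin count, minimum 10 bins, additive ε = 10⁻¹⁰ before
normalization, so disjoint supports stay finite), and a variance-gated test
flow — Brown–Forsythe (median-centered Levene) at 0.05, then one-way ANOVA
if variances are homogeneous, Kruskal–Wallis otherwise. The histogram KL
estimator carries a positive finite-sample bias of a few hundredths of a
nat on ~10⁴-sample inputs; it is suited to comparing divergences (e.g.
before/after correction), not to estimating small divergences precisely.

## Segmentation benchmarking

Predicted instances are matched one-to-one to ground-truth instances by
maximizing total matched IoU (Hungarian assignment); at each threshold,
matched pairs with IoU ≥ t − 10⁻⁹ count as true positives (the slack
admits exact matches at t = 1.0 despite floating-point IoU), unmatched or
below-threshold predictions as false positives, unmatched ground truths as
false negatives. F1 = 2TP/(2TP+FP+FN) is evaluated on the default grid of
eleven thresholds (0.5 to 1.0 in 0.05 steps) and aggregated across images
as the unweighted per-image mean; greedy matching and pooled aggregation
are available behind flags for comparison.

## The membrane-scene simulator

The synthetic module generates scenes with exact ground truth to test
everything else without external data. Non-overlapping spherocylinders
(default tip-to-tip length 4 µm; width fixed or uniform in a range, with
0.53–1.04 µm — the calibration range above — as the default; orientation
uniform) are placed by rejection sampling and rasterized exactly at a fine
render resolution (default 15 nm/px). Membrane fluorescence is rendered by
placing point emitters on a random 90% subset of each cell's cross-section
contour — the cut of a spherocylinder at height dz is again a stadium
outline with radius √(r² − dz²); planes at |dz| ≥ r contribute nothing —
and blurring with an isotropic Gaussian PSF of σ = 0.21 λ/NA (≈ 84.6 nm at
λ = 600 nm, NA = 1.49). This Gaussian is a deliberate simplification of a
full vectorial widefield PSF; it reproduces the ridge geometry that
matters here but not Airy rings or axial asymmetry. Z-stacks use widefield
image formation: every focal plane collects light from every membrane
slice, blurred by a defocus-broadened σ(Δz) = √(σ₀² + (0.5 Δz NA/n)²).
Optional Poisson shot noise and Gaussian read noise are seeded. Scenes are
rescaled to the output resolution (default 65 nm/px) by exact area-weighted
resampling (intensities) and per-pixel area-majority vote (labels);
ground-truth parameters are unchanged.

Apparent per-slice width — used by the focal-plane and projection
diagnostics — is measured as the separation of the two membrane-ridge
peaks flanking the axis (perpendicular intensity profiles at several
positions along the cell, parabolic sub-pixel peak refinement, median over
positions). This emulates active-contour ridge tracking; threshold-based
masks are unsuitable for the per-slice comparison because defocus blur
widens a thresholded footprint, compensating the geometric narrowing of
off-equator cross-sections.

What the simulator does *not* emulate: deconvolution artifacts, uneven
staining, membrane blobs and septa, camera-specific noise calibration,
cell crowding with touching membranes, curved or tapered cells. Passing
tests on these scenes therefore demonstrates the geometric and statistical
correctness of the pipeline, not segmentation robustness on real images.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest problem sizes — scenes of
a few cells on ~10 µm canvases, recovery suites of 50–150 cells, recovery
fits at 2 chains × 1000 draws (the default 4 × 3000 configuration is
exercised explicitly) — chosen so the full suite completes in well under a
minute while keeping Monte-Carlo noise far below the tested tolerances.
Degenerate inputs are defined conservatively: empty masks are valid and
yield empty outputs; ties in the branched-path median use the arithmetic
mean of the middle values; the rotation-robustness property is asserted at
6 nm/px, where rasterization quantization (±0.5 px over the cell radius)
sits below the 3% tolerance being tested.
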