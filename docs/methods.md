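# Methods

`atriaquant` estimates left-atrial (LA) fibrosis burden from a paired
acquisition: a bright-blood angiographic volume (CE-MRA-like) that delineates
the endocardium, and a late-enhancement volume (LGE-CMR-like) in which
fibrotic wall retains contrast and appears bright.  This note describes the
models and procedures the package implements, the parameters that matter,
what the synthetic phantoms do and do not emulate, and the numerical choices
made where the design was open.

## Pipeline model

The burden estimate is built from five components, run in sequence:

1. **Multilabel segmentation** of the angiographic volume into blood pool,
   veins+appendage, and mitral valve (plus background).  Two routes exist:
   a 2D multilabel U-Net applied slicewise, and a geometric route (region
   growing + medial-axis clipping + three-point valve sphere) that is also
   how training labels are produced.
2. **Rigid registration** of the two channels by maximizing normalized
   mutual information (NMI), with the segmentation transported into the
   enhancement frame by nearest-neighbour resampling.
3. **Reference statistics**: the blood-pool label is eroded by 3 voxels
   (3x3x3 box per unit of radius) and the mean and SD of the enhancement
   intensities over the eroded core become the normalization reference.
   The erosion keeps wall enhancement and partial-volume voxels out of the
   reference; inflating intensities within two voxels of the wall does not
   change the statistics.
4. **Surface projection**: the endocardial surface is extracted by marching
   cubes on the blood-pool mask (smoothed with a sigma = 1 voxel Gaussian
   before taking the 0.5 isosurface; this removes the voxel staircase and
   brings a digital sphere's area within ~1% of 4*pi*r^2).  At every mesh
   vertex the enhancement image is sampled along the outward unit normal
   from 1 mm inside to 3 mm outside the surface, at 0.25 mm steps with
   trilinear interpolation, and the maximum is kept (a transmural
   maximum-intensity projection; 3 mm approximates atrial wall thickness,
   1 mm inward absorbs residual registration error).  Rays leaving the
   image domain are clamped to their in-domain samples and the vertex is
   flagged; flagged vertices stay in the burden denominator, with the
   flagged fraction reported as a QC quantity.
5. **Thresholding**: with blood-pool mean m and SD s, a vertex is fibrotic
   under three standard rules — image intensity ratio IIR = projected/m
   above 0.97 (any fibrosis), IIR above 1.61 (dense scar), or projected
   above m + 3.3 s.  Burden is the percentage of surface elements above
   threshold.  "Surface elements" are counted as mesh vertices; an
   area-weighted variant (vertex weight = one third of incident triangle
   area) is available via `compute_burden(area_weights=...)`.  Because the
   rules are nested, the dense-scar burden can never exceed the
   any-fibrosis burden.

Vertices that bound the veins, appendage or valve are excluded from the
burden denominator: those structures are intrinsically enhanced and have no
atrial wall behind them.  A vertex is attributed to a structure if it lies
within one voxel of that structure's label (the vein/valve labels are
dilated by one voxel before sampling).  The one-voxel margin matters: at
the vein ostia the endocardial surface continues across the funnel where no
wall exists, and without the margin those vertices dilute the burden by
2-4 percentage points on phantoms; with a larger (2-voxel) margin, genuine
wall vertices adjacent to the ostia are lost instead.

## Segmentation network

The segmenter is a 2D U-Net written directly in numpy: `n_levels`
contracting stages (two 3x3 ReLU convolutions, 2x2 max-pool, features
doubling from `base_features`), a bottleneck, and a mirrored expanding path
(nearest-neighbour upsampling, channel-reducing convolution, concatenation
with the matching encoder features, two more convolutions), ending in a 1x1
convolution and softmax over 4 channels.  Input slices are resampled to
`input_size` x `input_size` pixels and min-max normalized per volume.
Training minimizes per-pixel cross-entropy with Adam; convolutions are
im2col matrix products and all gradients are analytic (verified against
central differences in the test suite).  The full-scale configuration is
320 x 320 with 5 levels; the desk-scale configuration used by the tests is
64 x 64 with 3 levels and 8 base features, which trains on ~200 phantom
slices in a few minutes on one CPU.

Training follows a two-phase curriculum: slices containing at least 50
pixels of *each* foreground label form a balanced subset trained first;
the remaining (mostly empty or single-label) slices join in phase 2.  This
prevents the abundant label-free slices from driving the net toward
under-segmentation.  Subjects, never slices, are split 70/10/20 into
train/validation/test.  Augmentation applies the same spatial transform to
image and labels: rotations up to 15 degrees, shifts up to 10 px,
horizontal flips (linear interpolation for the image, nearest for labels),
plus a +-10% intensity scaling of the image only.  At inference each
foreground channel is binarized at probability 0.5 (exactly 0.5 counts as
foreground), slices are re-stacked, and only the largest 26-connected
foreground component survives (ties broken by lowest flat voxel index).
A repeated random sub-sampling cross-validation harness (3 repetitions,
independent seeds) is provided.

## Geometric labeling

The blood pool is grown from a seed voxel: all 6-connected voxels within an
intensity tolerance of the seed value (a seed at or below the volume median
intensity is rejected as background).  The pool's medial model uses the
interior Euclidean distance transform (maximal-inscribed-sphere radii) and
the 3D skeleton as the medial vertex set.  Skeleton voxels with radius at
least `ostium_fraction` (default 0.5) of the body's maximal inscribed
radius form the chamber core; connected non-core skeleton components that
touch the core and extend at least 6 mm are branches (pulmonary veins,
appendage).  A large appendage lobe can exceed the core threshold and form
its own core island; branch roots are therefore restricted to the core
component containing the global radius maximum.

The ostium rule has two parts.  The radius-fraction gate finds the first
medial vertex (walking from the body outward) whose radius falls below the
fraction threshold; but because the medial radius decays gradually through
the chamber-to-vein funnel, that vertex can sit several millimetres inside
the chamber.  The ostium is therefore refined distally to the first vertex
whose radius comes within 0.5 mm of the minimum radius anywhere further
along the branch — the start of a tube's radius plateau, or a lobed
appendage's neck — which coincides with the geometric junction to ~2 mm on
phantoms.  The refinement can be disabled (`refine=False`), in which case a
saturating threshold (fraction = 1) returns the branch root.  Clipping
relabels the pool voxels on the distal side of the plane through the ostium
(normal = local centerline tangent, oriented away from the chamber) that
are connected to the branch's distal medial path; a clip that would
disconnect the remaining body, or move more voxels than it leaves, is
refused and the branch flagged.  Clipping and valve labeling only move
voxels between label codes, so total foreground is conserved, and
re-clipping is a no-op.

The mitral valve is labeled as the intersection of the blood pool with a
sphere whose great circle is the circumcircle of three user-placed points
on the orifice border (collinear points are rejected).

## Registration

NMI = (H(A)+H(B))/H(A,B) over a 64-bin joint histogram of the overlap; the
measure is symmetric, at least 1, and invariant to monotone intensity
rescaling up to binning.  The search over 3 rotations + 3 translations
(about the volume centre) is multi-resolution — 3 levels, downsampling
factor 2 with Gaussian pre-smoothing — with Powell refinement per level.

Two numerical choices matter.  First, the objective samples both channels
at half-voxel-offset points, so that *both* images are trilinearly
interpolated at every pose.  Sampling the fixed image on its own grid makes
exact grid alignment artificially sharp (interpolation smooths the noise of
the moving image everywhere else), which displaces the NMI optimum by up to
a degree; symmetric sampling removes the bias.  Second, the finest level is
multi-started from both the coarse-pyramid result and the initial guess,
because the coarse pyramid occasionally delivers a basin ~1 degree from the
optimum.  Sampling is strided to keep every objective evaluation near 130k
points regardless of volume size.  On phantoms, known offsets up to 5 mm /
5 degrees are recovered to ~0.1 mm and ~0.5 degrees; note that rotational
identifiability is limited by the chamber's near-ellipsoidal symmetry, and
a noise realization can displace the true NMI optimum itself by 1-2 degrees
without moving the burden estimate more than a fraction of a point.

## Statistics

Segmentation overlap is summarized per label from the voxel confusion table
(Dice, accuracy, sensitivity, specificity, precision).  Scalar agreement
between two measurement routes reports Pearson r, RMSE, Bland-Altman bias
(mean of test minus reference) with 1.96 SD limits, mean absolute and
relative errors, and ICC.  The ICC form is ICC(1,1) — one-way
random-effects, single rater, absolute agreement (in the one-way model
absolute agreement is implied):

    ICC = (MSB - MSW) / (MSB + (k-1) MSW)

with 95% confidence bounds from the F distribution
(F = MSB/MSW, df = (n-1, n(k-1))); the implementation matches pingouin's
one-way form to 6 decimals in the tests.  Agreement bands: 0.41-0.60
moderate, 0.61-0.80 good, above 0.80 excellent.  Shapiro-Wilk, one-way
ANOVA and logistic-regression ROC/AUC are routine methods delegated to
scipy/scikit-learn behind `cohort_report`.

## Synthetic phantoms

The phantom emulates the paired acquisition with known ground truth: a
thin-walled ellipsoidal body (default semiaxes 30/25/20 mm, wall 3 mm),
four tubular veins (radius 5 mm, length 25 mm) at fixed posterior
superior/inferior positions with seeded angular jitter up to 3 degrees, an
appendage modelled as an oblate lobe on a short neck, and a valve orifice
(12 mm sphere at the inferior pole) where the wall is open.  Intensities:
lumen Gaussian (mean 100, SD 10) in both channels; wall 60 and enhanced
wall 200 in the enhancement channel; additive Gaussian noise (SD 5) clipped
at zero.  With the mean + 3.3 SD threshold near 137, enhanced wall is
unambiguous while healthy wall and blood stay below — the phantom tests
geometry and bookkeeping, not threshold sensitivity.  The enhancement
channel is generated on a grid rigidly displaced by a known offset (default
2/-3/1.5 mm, 2/-1/1.5 degrees) by evaluating the analytic geometry at
inverse-transformed coordinates, so there is no resampling error in the
ground truth.

Fibrosis is painted as a contiguous geodesic cap on the posterior wall,
grown voxel by voxel (in order of angular distance from the cap axis, ties
broken by voxel index) until exactly the requested fraction of body-wall
voxels is covered; the true burden is that attained voxel fraction.  The
burden the pipeline measures is a *surface* fraction, which differs from
the wall-voxel fraction by curvature weighting and by the accounting of the
ostium exclusion zones; on phantoms the two agree within ~2 percentage
points across painted fractions 10-50%, inside the 3-point band that
matters for classifying patients into burden strata.

What the phantom does not emulate: MR physics (inversion recovery, bias
fields, navigator artifacts), anatomical variability (vein count and
branching, appendage morphology), wall-thickness variation, and intensity
overlap between fibrotic and healthy wall.  Passing phantom tests therefore
demonstrates the correctness of the geometry, registration and scoring
machinery at realistic noise levels — not clinical segmentation or
threshold performance on patient data.

A simulated second observer perturbs a label map by adding a smooth random
field to the signed distance of each boundary and re-thresholding; the
default amplitude (2 mm boundary jitter, 2 mm ostium jitter) is calibrated
so that blood-pool Dice against the truth lands near 0.85, the human
interobserver level, on the standard test phantom.

## Problem sizes and defaults

The default phantom grid is 160^3 at 1 mm; the full pipeline (registration
included) runs in ~40 s on one CPU at that size, well inside a 3-minute
per-case budget.  The test suite and the acceptance script use a 96^3
phantom with the same topology at ~60% scale (semiaxes 18/15/12 mm, wall
2.5 mm) and a 76^3 variant for registration recovery, chosen so the whole
suite completes in minutes while leaving every geometric relationship
(wall thinner than the projection length, veins long enough for the
centerline, erosion-safe pool) intact.  Network experiments use 64 x 64
slices, 3 levels, 8 base features, ~200 slices, ~400 optimizer steps.

## Known limitations

* The maximum-intensity projection discards transmural distribution; a
  thick or fatty wall beyond 3 mm is invisible by construction (the
  projection-length sweep from 1 to 6 mm is provided to check stability).
* The ostium localization assumes roughly tubular appendices; exotic
  branching (common ostia, accessory veins) is clipped at whatever the
  radius profile identifies as the neck.
* Burden comparisons against the phantom's wall-voxel truth carry an
  irreducible ~1-2 point geometric accounting difference (surface vs
  volume fraction); the package reports surface fractions, as the
  measurement defines.
* ICC confidence bounds use the exact F-interval, which is slightly
  liberal for very small tables (n < 10).
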