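# Methods

## The model

`stackellipse` segments the uterus (including the cervix) in 3-D
transabdominal B-mode ultrasound by modelling the organ as a *stack of
ellipses*: a sequence of elliptical cross-sections on semi-axial planes that
fan along the curved fundus-to-cervix path.  The representation rests on two
anatomical observations: uterine cross-sections taken orthogonal to the
organ's long axis are approximately elliptical, and the uterus is hypoechoic
(darker) relative to the surrounding tissue, so the expected contrast
polarity of its boundary is known everywhere.

An ellipse is parameterised as `(c1, c2, a, b, phi)` satisfying

    (x - c1)^2 / a^2 + (y - c2)^2 / b^2 = 1

in plane coordinates, where `a` is the semi-axis along anatomical left-right
(LR) and `b` the semi-axis along the in-plane anchor direction.  First-guess
ellipses are axis-aligned (`phi = 0`); fitted ellipses may rotate.

### Training: the axis model

Gold-standard 3-D contour surfaces are cut by the same semi-axial planes the
segmentation phase uses, each cross-section polygon is fitted with a direct
least-squares ellipse, and the pooled `(a, b)` pairs from all patients and
slices enter one unweighted ordinary least-squares regression

    a = m * b + K.

The package ships a default population model `a = 1.01 b + 11.3` (R^2 =
0.60) so segmentation is usable without retraining; per-patient fits are
available as a diagnostic only and never enter the model.

### Segmentation

1. **Initialisation.**  The observer contours the uterus on one mid-sagittal
   slice and marks four landmarks — fundus-top, cervix-top, cervix-bottom,
   fundus-bottom — splitting the closed contour into the top half, the
   cervix end face, the bottom half, and the fundus end face.  Anchor points
   are placed arclength-uniformly on the top half, the same number on the
   bottom half (count = ceil(top-half arclength / slice spacing), at interior
   fractions (i+1/2)/n), and paired in fundus-to-cervix order.  Each pair
   defines a slicing plane spanned by the anchor chord and the LR axis
   through the chord midpoint; the chord supplies the minor semi-axis seed
   `b = |top - bottom| / 2` and the ellipse centroid, and the axis model
   supplies `a`.  The end-face segments delimit the slicing extent; pairing
   them with each other would produce longitudinal pseudo-slices with `b`
   close to half the organ length, so they generate no planes.
2. **Directional edge map.**  Each plane resamples the volume trilinearly
   (pixels outside the field of view are masked and contribute nothing —
   smoothing is mask-normalised so the volume border itself produces no
   edge).  With `V1` the sigma-smoothed image, `J` the outward unit gradient
   of the signed distance map of the initialisation ellipse, and `d` the
   unsigned distance to it,

       f = |grad(V1) . J|^2 * R    where grad(V1) . J > 0, else 0
       R = (1 - (d/max d)^k) * exp(-(d/max d)^k),

   keeping only dark-to-bright (inside-to-outside) boundaries and damping
   edges far from the prior.  `max d` is taken per slice over its own grid.
3. **Radial peak search.**  Each of the `n_points` initialisation points
   samples `f` along the ray from the ellipse centroid through itself, over
   a window of total length `r` pixels centred on the point (1-pixel steps,
   bilinear interpolation).  The point moves to the strict local maximum
   (value > 0) nearest to it; equidistant ties prefer the inward peak
   (over-reach into bright far tissue is the commoner failure); with no peak
   the point stays, so a missing boundary defaults to the shape prior.
4. **Regularisation.**  A direct least-squares ellipse is fitted to every
   provisional contour, damping outliers that latched onto spurious
   boundaries; a degenerate fit falls back to the first-guess ellipse with a
   warning.
5. **3-D assembly.**  Final ellipses are sampled, mapped to world
   millimetres, and enveloped by a single closed triangulated boundary with
   a concavity ("shrink factor") parameter; see *Numerical choices*.

The pipeline is deterministic and has no complete-failure mode: each
per-slice exception degrades that slice to its first guess.

## Tunable parameters

| name | default | units | role |
|------|---------|-------|------|
| `sigma` | 4 | semi-axial pixels | Gaussian smoothing std of `V1` |
| `k` | 1 | — | distance-weight exponent; smaller penalises far edges harder |
| `r` | 29 | semi-axial pixels | total radial search length (forced odd) |
| `shrink_factor` | 0.5 | — | boundary concavity; 0 = convex hull |
| `slice_spacing` | 2 x voxel | mm | anchor spacing; denser = more slices |
| `n_points` | 180 | — | contour samples per slice (1 per 2 degrees) |

`sigma` and `r` are expressed in pixels of the resampled semi-axial grid,
whose spacing defaults to the smallest voxel spacing, so at 0.58 mm voxels
the search window is about 17 mm.  The `sigma`/`k`/`r` defaults are the
values used for every segmentation in the validation study this package
reimplements; `shrink_factor` and `n_points` are unstated there and were
fixed once at the values above.

## The ellipse fit

The "numerically stable direct least squares" fit (the partitioned
Halir-Flusser formulation of the Fitzgibbon ellipse-specific conic fit) is
implemented in-package: data are centred and scaled, the constraint
`4 a1 a3 - a2^2 = 1` guarantees an ellipse, and the conic is converted to
centre/axes/rotation via the 2x2 quadratic-form eigendecomposition.  It is
non-iterative, recovers noise-free ellipses to ~1e-15 relative error, and
signals degenerate (e.g. collinear) input distinctly.  An off-the-shelf
implementation was rejected after it produced complex rotation angles on
valid inputs.

## 3-D boundary with a shrink factor

The final surface is the boundary of an *alpha complex*: Delaunay
tetrahedra of the contour point cloud with circumradius at most
`alpha_crit / shrink_factor` are kept, where `alpha_crit` is the smallest
radius whose complex is face-connected and covers every input point;
`shrink_factor = 0` keeps everything (the convex hull).  Because the contour
cloud is a hollow tube, the raw Delaunay interior contains tetrahedra whose
circumradius scales with organ width — the same scale as the tetrahedra
that bridge the anteverted concavity, which would make carving and
interior-filling inseparable.  Each slice therefore contributes a sparse
interior scaffold (concentric sub-ellipses at ~3 mm spacing); scaffold
points are strictly interior and set `alpha_crit` by the surface sampling
density instead.  The boundary of a tetrahedron union is always edge-closed;
it can be vertex-pinched at extreme shrink values, which the voxeliser and
metrics tolerate (see below).

## Evaluation metrics

* **DSC** `= 2|A n B| / (|A| + |B|)` on voxelised masks sharing one grid
  (the joint bounding box padded 5 mm, at the source voxel spacing by
  default).  Voxelisation rasterises exact triangle-plane cross-sections
  slice by slice with even-odd filling; it refuses surfaces with open
  boundary edges but accepts vertex-pinched closed ones, for which parity
  filling remains exact.  Two empty masks give DSC 1 by convention.
* **MSSD**: mean nearest-neighbour distance between surface point sets,
  sampled at mesh vertices densified by midpoint subdivision to 0.5 mm
  edges.  The directed version averages over the first surface; the default
  reported value is the symmetric mean of both directions (`--directed`
  selects the one-way value).
* Cohort summaries report median and IQR (Q3 - Q1, linear-interpolation
  quantiles), per patient and overall.

## The phantom generator

The generator emulates exactly the image properties the algorithm assumes,
with exact ground truth:

* **Shape**: an anteverted-uterus-like tube — quadratic mid-sagittal
  centerline bending ~60 degrees from SI toward AP over ~55 mm, minor
  semi-axis tapering 15 -> 9 mm toward the cervix, major semi-axis following
  `a = 1.01 b + 11.3` with 1.5 mm per-slice jitter.  The truth mesh is
  assembled by the same boundary operator the segmentation uses.
* **Appearance**: piecewise-constant intensity (interior 50, background
  100, i.e. contrast ratio 0.5), Gaussian PSF of 1 mm, unit-mean
  multiplicative Rayleigh speckle (the fully-developed-speckle
  approximation), optional angular shadow wedges; 0.58 mm isotropic voxels.
* **Initialisation**: the exact mid-sagittal cross-section of the truth
  stack with landmarks at the four anatomical extremes; observer
  variability is emulated by a smooth random radial perturbation of
  bounded amplitude (redrawn in the rare case it self-intersects).
* All randomness flows from a single integer seed through named
  sub-streams (truth / speckle / initialisation), so cases are bit
  reproducible.

What the phantom does **not** model: sector-geometry scan conversion,
attenuation and focusing gradients, neighbouring organs (bladder, bowel
gas), tumour-distorted anatomy, and inter-observer landmark semantics.
Passing the phantom suite therefore demonstrates the pipeline's geometric
and contrast logic under speckle, not clinical-grade accuracy; the clean
phantom boundary is why phantom DSC/MSSD are substantially better than the
agreement reported on patient data for this class of method.

## Numerical choices and degenerate inputs

* Gradients use central differences; direction vectors with magnitude
  below 1e-6 are zeroed (medial axis).
* Image gradients smaller than ~1e-9 of the slice's intensity range are
  treated as zero before the edge-map case split, so a uniform (or
  out-of-view) region can never emit floating-point-noise peaks.
* Peak = strict local maximum with positive value; plateaus take their
  centre sample; a point never moves farther than r/2 pixels.
* Anchor pairs of zero length, planes missing the training surface,
  cross-sections with < 5 points, and degenerate provisional fits are
  skipped or degraded per slice, each with a recorded warning.
* Axis regression with identical minor axes raises; a constant major axis
  yields slope 0 with R^2 = 0 by convention.
* Problem sizes used by the shipped checks (chosen to keep a full run in
  minutes on one core): default phantoms of ~40 truth slices at 0.58 mm
  voxels; 20 speckled seeds in the test suite and 10 in
  `scripts/acceptance.py`; 100 and 50 simulated training cohorts
  respectively; 1000 random ellipses for fit fidelity.

## Known limitations

* Slicing planes are derived from arclength-proportional anchor pairing;
  where the top and bottom contour halves have very different local
  curvature the chords tilt away from orthogonality to the centerline, and
  the fitted per-slice ellipses describe those oblique cuts.  The 3-D
  surface remains correct (oblique cuts of the true surface still lie on
  it), but per-slice `(a, b)` comparisons against generating values are
  only clean on straight stacks.
* A single global axis model cannot capture per-patient axis-ratio
  variation; it only seeds the search, which recovers `a` from image
  evidence within `r/2` pixels.
* The alpha-complex boundary is not guaranteed vertex-manifold; meshes are
  watertight in the edge-closed sense.
* Contrast inversions (a hyperechoic uterus, e.g. bulky tumours) violate
  the directional assumption by design; the edge map is zero there and the
  output degrades toward the shape prior.
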