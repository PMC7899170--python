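# Methods

This note documents the models, the synthetic data they are validated on,
the numerical choices, and the known limitations of `endocal`.

## Camera model and distortion

The simulator's forward model is a radially symmetric fisheye projector.
A scene point at in-plane radius `r_mm` on a target plane perpendicular to
the optical axis at working distance `w` subtends the off-axis angle
`theta = arctan(r_mm / w)` and lands at pixel radius

    r_px(theta) = c1*theta + c3*theta^3 + c5*theta^5

from the FOV centre, with the azimuth preserved exactly. This family was
chosen deliberately: it respects the radial symmetry established for
flexible endoscopes, produces realistic centre-to-periphery compression,
and is *not* in the polynomial-in-(w, r_p) family fitted downstream, so the
calibration tests are not tautological.

The three coefficients are fully determined (3x3 linear solve,
`camera.calibrate_distortion`) by three published pixel-spacing anchors of
the real endoscope: for a 0.5 mm circular grid, the two smallest circles
are 30 px apart at `w = 2.87` mm and 35.5 px apart at `w = 2.24` mm, and
ring spacing near the FOV border falls to ~20 px at `w = 2.87` mm.  The
periphery anchor is attached to the 2.0->2.5 mm ring pair, which places the
fifth ring at ~130 px — just inside the 135 px FOV rim, consistent with the
benchtop protocol of keeping the largest visible circle near the border.
The resulting defaults: `(c1, c3, c5) = (200.832, -97.221, 115.408)`,
FOV half-angle ~42.4 deg, sensor 288x280 px, FOV centre (144, 140),
radius 135 px, fiducial protrusion at 30 deg.

Conventions: pixel centres on integer coordinates, x rightward, y
*downward* in storage, 0-based; all polar math is done in FOV-centred,
y-up coordinates.

## Laser projector

49 rays diverge from a projection channel offset 0.5 mm from the pinhole
along +x.  Column aiming angles span 1..21 deg (the fan is tilted to the
offset side so that no ray crosses the optical axis anywhere in
`w in [2, 35]` mm — every dot's pixel radius is then monotone in `w`, as in
the physical device, and the radius-based baseline decoder remains
well-posed).  Row angles span -14..+14 deg with the top row at +24 deg,
most oblique, which qualitatively reproduces the reported degradation of
top-row points.  All values are simulator conventions, not claims about
the physical instrument; the channel offset is smaller than a typical
physical channel spacing because the anchor-calibrated FOV half-angle
(~42 deg) would otherwise push the pattern out of field at `w = 2` mm.

## Rendering

Scenes are rasterized at 4x supersampling and box-downsampled.  Grids and
line targets are dark ink (0.10) on bright background (0.85), 2 px line
width; laser spots are Gaussian (sigma 1.2 px, amplitude 0.9).  Laser-only
frames use a dim 0.25 interior (light source off).  Line-segment scenes
recorded *with* the laser are exposed for the much brighter laser light:
background 0.45, ink 0.05 — without this, clipping at full scale would
leave the spots ~0.04 above background after preprocessing and dot
segmentation would be physically unrealistic rather than merely hard.
Outside-FOV pixels are 0.02; a bright fiducial disc (radius 5 px) protrudes
from the rim.  Intensity noise is off by default; Gaussian noise can be
enabled for robustness experiments.

Ground truth sidecars carry exact projected circle radii (px and mm), dot
centres, line endpoints and sector angles.  The four generated sets follow
the benchtop design: Set 1 — 65 grid recordings over `w in [2, 32]` mm in
three sweeps (22+22+21), spacing 0.5/1/2 mm on `[2,10)/[10,20)/[20,32]`;
Set 2 — 72 laser frames over `[2, 35]` mm in four sweeps; Set 3 — a
24-sector grid at 6.16/13.20/19.54/26.44 mm; Set 4 — 105 line segments
(5/10/15/20 mm at 20.18 mm, plus 5 mm at 5.12/9.98/14.98/20.18 mm, 15
random placements each).  Grids have 10 rings: with ~9–10 detected circles
per recording this reproduces the reported ~600-point calibration sample
(596 on the synthetic analog vs 612 in the benchtop study) while keeping
peripheral rings resolvable.

## Segmentation

* Preprocessing: temporal mean, then Gaussian smoothing.  The published
  description ("a Gaussian filter with a size of 2 pixels") is ambiguous;
  it is interpreted as sigma = 2 px, kernel truncated at 4 sigma, and is
  configurable.
* FOV: Otsu threshold, hole filling, largest component; the radius is the
  median boundary distance (robust to the fiducial bump), the fiducial
  angle the circular mean of boundary points protruding > 2 px beyond the
  rim.
* Circles, coarse stage: a 9-px strip through the FOV centre is averaged
  across its width; sub-pixel local minima (prominence >= 5% of the strip's
  dynamic range, parabolic refinement) are paired left/right by distance
  from the centre (partner tolerance 3 px); the pair mean gives the centre
  coordinate and half the pair difference the radius, row-wise and
  column-wise; the coarse radius is the mean of the two.  Unpaired minima
  are dropped with a warning.
* Circles, fine stage: exhaustive search over the +-1 px / 0.25 px lattice
  (9^3 candidates).  Each candidate builds a 1-px-wide ring mask and sums
  the Sobel gradient magnitude under it; the *minimizing* triple wins.
  Minimization is correct here because the dark circle line is an
  intensity ridge — the gradient magnitude vanishes on its centreline
  between the two edges.  A maximize-on-edge variant is available via
  `mode="edge"` for single-edged circles.
* Laser dots: Otsu threshold computed on the upper half (>= median) of the
  in-FOV intensities (works for both dark-background laser-only frames and
  bright-background laser+light frames), connected components with minimum
  area 3 px, intensity-weighted centroids.  Dots are labelled row-major
  1..49 after rotating detections into the grid-aligned template frame
  (the device constant: at standard angle 30 deg the 7x7 grid is
  axis-parallel); rows are chunked by template-y, columns ordered by
  template-x, and missing dots are flagged absent.
* Radial lines: Hough transform on the ink mask seeded at 0.25 deg
  resolution, keeping lines passing within 4 px of the FOV centre.
  Concentric-ring ink is suppressed beforehand by a gradient-orientation
  test (ring edges have radial gradients, line edges tangential ones).
  Each Hough seed is refined by an iterated second-moment orientation fit
  of the ink pixels in a +-2 px band about the line (centre region d <= 20
  px excluded); duplicates are merged, since opposite sector boundaries
  share a line (12 distinct lines for 24 sectors).

## Working-distance decoding

`WorkingDistanceEstimator` takes a matrix of template-normalized dot
coordinates (reference FOV radius 135 px — projections are therefore in
template-pixel units) and the true distances.  For each point, the PCA
method centres the track, takes the leading eigenvector of Q Q^T (sign
fixed so the projection increases as `w` decreases; isotropic ties break
toward +x) and fits `w = b1*exp(b2*v) + b3*exp(b4*v)` by nonlinear least
squares.  Initialization is deterministic multi-start: a log-linear fit of
`w` on `v` seeds the dominant term, the residual mean seeds the second,
and three sign/scale perturbations guard against local minima; the lowest
SSE wins.  Fits are accepted only with >= 4 observations; monotonicity of
each G over its training range is checked numerically
(`monotone_fraction_`).  The original baseline uses the polar radius
instead of the PCA projection and excludes the top row (points 1–7) by
default.  Per-point predictions are aggregated by the median — the study
never states how a single estimate is formed from 42–49 per-point values;
the median is robust to occluded or mislabelled dots and is recorded as a
package decision.

## Horizontal calibration and measurement

The non-uniform surface is linear in its coefficients and fitted by least
squares on the scaled basis `(w/w_scale)^k (r_p/r_scale)^l`, `k = 1..M`,
`l = 1..N`; scaling (defaults: training maxima) is purely for conditioning
— degree-8 monomials on raw pixel radii are numerically hopeless — and is
applied transparently at prediction.  As printed, the double sum starts at
k = l = 1: no intercept and no pure-`w`/pure-`r_p` terms, hence
`F(w, 0) = 0` exactly (zero pixel length must mean zero mm).  Model
selection searches `M, N in 1..8` with 10-fold cross-validation; folds are
assigned at the *recording* level (all circles of one image share a fold)
to prevent leakage between circles of the same frame — the fold unit is
not stated in the study and is a package decision.  On the synthetic
analog the selection lands on low `M` (the simulator's exact inverse is
`w * g(r_p)`, separable and linear in `w`); the search range still covers
the degree-(5,5) choice reported for the physical device, where sensor
noise and optics make higher `w`-orders useful.

The uniform baseline fits `gamma(w)` by a straight line through the
per-recording pixel sizes of the largest visible circles.  Its
cross-validated evaluation follows the benchtop protocol: each fold's
model is scored on the held-out recordings' circles *plus* the training
recordings' smaller circles (which the gamma fit never saw).

Radial measurements evaluate the surface directly; general measurements
use the law-of-cosines decomposition with the central angle normalized to
[0, 180] deg (the cosine is insensitive to the choice).  Endpoints at the
FOV centre degenerate to a radial measurement of the other endpoint.
Predictions more than 10% outside the training domain attach a warning.

## Robust statistics

The one-way comparison of error groups uses a trimmed-means bootstrap
ANOVA (trim 0.2, 1000 bootstrap samples): a heteroscedastic F-like
statistic on 20%-trimmed means with winsorized-variance weights, with the
null distribution obtained by resampling the trimmed-mean-centred groups.
Only the trim level and bootstrap count are prescribed by the source
protocol; the concrete statistic is a package decision and is isolated in
`evaluate.robust_anova` so it can be swapped.

## What the synthetic validation does and does not show

The generator reproduces the geometry of the benchtop datasets (set sizes,
distance sweeps, grid spacings, ring-spacing anchors) under noiseless,
perfectly perpendicular imaging with exact ground truth.  Passing tests
therefore demonstrate the *correctness of the algorithmic chain* — that
segmentation is sub-pixel accurate, that the selected surface inverts the
distortion to ~6 µm held-out radial error, that central angles survive the
distortion, and that end-to-end general measurements with laser-decoded
distances stay well inside the published error levels (0.025 mm radial CV
MAE, 0.27 mm mean |error|, 0.6 deg angle spread).  They do not certify
performance on real tissue or real optics: sensor noise, illumination
gradients, defocus blur at long distances, chromatic effects, target tilt
and manual-segmentation variability are all absent.  One published figure
is *not* matched for this reason: the uniform model's |error|-vs-w Pearson
correlation reaches ~0.73 on the noiseless analog versus 0.76 on the
physical data, where pixel-level noise scaled by gamma(w) (which grows
with w) adds a positively correlated error component.

Other knowns limitations: the law-of-cosines treats the scene-side
triangle as planar Euclidean, exact only for flat perpendicular targets;
tilted surfaces are out of scope.  The FOV/dot segmentation of the
original instrumentation study is not restated in the source material;
the implementations here are faithful stand-ins.  Why top-row laser points
degrade accuracy on the physical device is unexplained; the simulator
only mimics it geometrically (most oblique rays).
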