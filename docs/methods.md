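# Methods

## The problem

Root system architecture of plants grown flat on germination paper is
measured from photographs: the image is segmented into root vs background,
the root mask is thinned to a centerline, and lengths, diameters and derived
traits are read off the skeleton.  Every stage can bias the result —
uneven flash illumination, specular glare on the cover foil, threshold
choice, thinning artifacts, staircase digitization.  This package implements
the full chain and, crucially, a synthetic generator whose images come with
analytically known lengths, so the chain's accuracy is measurable rather
than assumed.

## Artificial root images

A vector root system is a set of node chains (x, y, diameter in mm; origin
top-left, y downward).  The centerline through the nodes is a natural cubic
spline parameterized by chord length (piecewise linear for chains of 2–3
nodes, where a cubic is underdetermined).  Rendering places a Gaussian
intensity cross-section perpendicular to the centerline with its full width
at half maximum equal to the local diameter:

    I(p) = background + amplitude * exp(-r(p)^2 / (2 sigma^2)),
    sigma = d / (2 sqrt(2 ln 2)),

where r(p) is the distance from pixel center p to the nearest centerline
point (densely resampled at a quarter-pixel step).  Overlapping roots
composite by maximum — a root is opaque, crossings do not brighten.  Roots
render bright on a darker background, matching the red channel of pale
roots on blue/grey paper; dark-root imagery is handled by the segmentation
polarity instead.  Ground truth is the spline arc length, stable to <0.1%
under step refinement.

Defaults mirror the imaging rig being emulated: 0.13 mm/px (a 490-mm field
over a 3744-px sensor side), 8-bit tonal range, background 40, amplitude
200 (high contrast), no noise.  The `ragged_edges` flag perturbs the
rendered width along the centerline with seeded Gaussian jitter
(sd = 20% of the local diameter), reproducing the ragged mask boundaries
that root hairs and reflections cause in real images; it exists to study
thinning artifacts, not to model hair morphology.

### The generator

`generate_root_system` emulates a young maize system on a sheet: axile
roots (diameter ~ U(0.6, 1.2) mm, constant per root) start near the top
edge and random-walk downward with small angular increments (sd 0.12 rad
per 6-mm step, clamped to ±0.45 rad from vertical, reflected at the sheet
margins).  Laterals attach at Poisson-distributed arc-length positions
(rate `laterals_per_cm`), exactly on the parent spline, emerge at 45–80°
from the parent tangent, and bend slowly toward vertical (angle decays by
factor 0.92 per step plus noise).  The slow decay matters: laterals that
collapse onto the vertical quickly end up running inside their parent's
rendered width, which no image-based method can recover — real laterals
hold an oblique course over the first centimeters.  Lateral diameters are
U(0.26, 0.47) mm, lengths U(8, 20) mm, truncated at the sheet margin.

What the synthetic images do *not* contain: root hairs as structures,
texture of the paper, moisture gradients, curved crossings with partial
transparency, or time.  Accuracy numbers on clean renders are therefore an
upper bound for real images; the ragged-edge and noise options probe the
degradation directions but are not calibrated to any real camera.

## Preprocessing

Order: flat-field each flash image, fuse, extract one channel.  The
flat-field model is divisive (vignetting of flash lighting is
multiplicative): medians over a coarse grid of `kernel_scale` windows
reject thin bright roots, border windows are anchored at their centroid so
linear gradients extrapolate correctly, the grid is interpolated to full
resolution and Gaussian-smoothed (σ = kernel/8) behind an odd-reflection
pad.  The corrected image is rescaled to preserve the input mean and
clipped to the tonal range; all arithmetic is float, quantization happens
only at file output.  Minimum-tonal fusion is the pixelwise minimum of the
pair — commutative, associative, idempotent — and removes any artifact
present in only one image.  The default output channel is red.

## Segmentation

* `global_threshold`: root_dark means pixel < t (pixels at t are
  background); root_bright is the mirror image.  `auto_threshold` selects t
  by the Otsu criterion on the exact tonal histogram and returns a value
  strictly between the two classes (lower-class boundary + 0.5).
* `adaptive_threshold`: the image is tiled into non-overlapping
  `block_size` squares (edge blocks smaller); a pixel is root when its
  polarity-signed deviation from the block mean exceeds
  `proportion · (2^bit_depth − 1)`.  A `smooth=True` variant replaces tiled
  means with a per-pixel moving average of the same window; both are
  exposed because the tiled-vs-overlapping semantics of the original tools
  are not documented anywhere.
* `double_adaptive_threshold`: local means m(s) over a ladder of
  neighborhood sizes; root requires both a deviation above
  `min_change · range` at some size and monotone growth of the deviation
  with s.  The monotonicity requirement suppresses paper-texture noise and
  rejects the interior of wide plateaus (where m(s) ≈ pixel for all s).

Defaults: root_bright, block 64 px, proportion 0.1, sizes (5, 15, 31),
min_change 0.1.  Lengths are insensitive to the exact operating point
(the skeleton of a slightly wider ribbon is the same centerline), but
distance-transform diameters are not: they are accurate when the mask is
cut near half amplitude.  When the rendered amplitude is known, use a
global threshold at background + amplitude/2 for diameter work.

Mask cleaning removes 8-connected components below `min_object_px`
(default 20 px ≈ 2.6 mm of 2-px-wide object at 0.13 mm/px).  Hole filling
is available but off by default: crossing roots legitimately enclose
background regions, and filling them collapses the network into blobs.

## Measurement

Thinning uses topology-preserving 8-connected skeletonization.  Terminal
branches shorter than `max_spur_px` (default 5) that end at a junction are
pruned iteratively — these spurs are thinning artifacts of ragged mask
boundaries and inflate length; a re-thinning pass after pruning removes
the one-pixel bumps a diagonal spur can leave behind.

Two length metrics are provided deliberately:

* **Chain-code length** — orthogonal steps count 1 px, diagonal steps √2,
  summed over all adjacent skeleton-pixel pairs.  It is simple and exactly
  checkable against edge enumeration, but on digitized smooth curves it
  systematically overestimates: a straight run at 22.5° reads +8.2%, and
  averaging over orientations gives roughly +5%.  No pruning can remove
  this bias; it is a property of the metric, not of the skeleton.
* **Smoothed polyline length** (the headline estimator used by the batch
  pipeline and benchmark) — the skeleton is traced into branch polylines
  between endpoints/junctions, each polyline is smoothed with a 5-point
  moving average (endpoints pinned), and Euclidean segment lengths are
  summed.  This removes the staircase bias (a digitized 22.5° line is
  recovered to <2%) while leaving straight orthogonal/diagonal runs
  untouched.  The window is short relative to any real root curvature
  (5 px = 0.65 mm vs centimeter-scale bending radii), so shape is not
  blunted.

Diameter at a skeleton pixel is (2·EDT − 1) pixels, where EDT is the
Euclidean distance transform of the mask; the −1 accounts for the half
pixel between a boundary-pixel center and the true boundary (a 5-px bar
reads 5 px, a digitized disk of radius r reads 2r).  Mask digitization
quantizes the width by up to half a pixel, so even-width phase-aligned
bars read one pixel low; the practical accuracy is ±1 px.  Each chain-code
step is assigned to the diameter class of its endpoint-mean diameter;
class lengths partition the chain-code total exactly.  The axile/lateral
split defaults to 0.5 mm.  Surface and volume use the cylinder model
(π d L and π (d/2)² L per step).  `resolution_mm_per_px` and
`min_detectable_diameter` implement the field-of-view arithmetic and the
three-pixel detectability rule of thumb.

## Spectra

Sensor counts scale linearly with exposure time, so curves are first
rescaled by t_reference/t_sample, then divided pointwise by the
exposure-corrected white standard (spectralon).  Band contrast is the
ratio of band-mean reflectances, root over paper.  The channel
recommendation scores each candidate band by the minimum over papers of
|log contrast| — the worst paper in the batch decides, and |log| treats
root-bright and root-dark separations symmetrically — with ties broken
toward the longer wavelength.  Band edges (blue 450–490, green 520–560,
red 620–720, NIR 790–1000 nm) are configurable; only the visible bands are
candidates by default because an RGB camera has no NIR channel.

`make_fixture_spectra` builds a deterministic batch on a 2-nm grid with
the qualitative structure of a measured root/paper set: three strongly
blue/grey papers at exactly half the root's reflectance between 560 and
720 nm (blue peak, NIR rise), a light-blue paper brighter than the root
with blue/NIR maxima, a white paper at twice the root everywhere, raw
counts including a synthetic lamp/sensor response, per-sample exposure
times (0.21 s reference, 0.4 s blue/grey, 0.3 s light blue, 0.25 s white)
and 0.2% multiplicative noise.  Only the encoded ratios are meaningful;
absolute reflectance levels are synthetic.

## Evaluation

`repeatability` estimates the operator-repeatability statistic
R² = σ²_image / (σ²_image + σ²_error) from a complete image × user table by
method-of-moments ANOVA on the balanced two-way layout: σ²_error is the
interaction/residual mean square, σ²_image = (MS_image − MS_error)/n_users,
negative estimates truncated at zero.  For balanced tables this has the
same expectation as a REML fit while staying closed-form; simulation
recovery (true ratio 0.9, 200 images × 3 users) is within ±0.03.

`run_benchmark` is the end-to-end experiment: n systems (default 10,
cycling 1–3 axile roots and 0.5–2 laterals/cm for a spread of total
lengths) are rendered noiselessly at 0.13 mm/px, segmented with the
default adaptive threshold, cleaned, and measured by two independent
backends — the pruned-skeleton pipeline (smoothed length) and a vector
replay that integrates the generating centerlines at a 0.13-mm step.  Both
are scored against the analytic truth, and backend agreement is the
squared Pearson correlation of per-image lengths.  Everything derives from
one seed; a run is bit-reproducible.

Problem sizes were chosen so the whole suite and the benchmark run in
seconds on a single core: 60 × 80 mm sheets (≈ 460 × 615 px), 10 images per
benchmark.  Larger sheets change none of the per-pixel mathematics.

## Known limitations

* Overlapping roots are rendered opaquely; centerline buried inside
  another root's width is unrecoverable by any image-based backend, so
  dense systems bias image-based length slightly low while the vector
  replay is unaffected.  At the default densities this stays within the
  5% envelope.
* Per-root attribution of skeleton branches (topology reconstruction) is
  out of scope; axile vs lateral separation is by diameter class only.
* The double-adaptive threshold cannot use large `min_change` values on
  wide roots: the local mean at the largest neighborhood already contains
  much of the root's own mass, capping the attainable deviation.
* Diameters from a mask cut far from half amplitude are systematically
  wide; the pipeline reports them anyway because length, the headline
  trait, is unaffected.
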