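# Methods

This note records the models, parameter conventions, numerical choices
and known limitations behind `phasetrack`.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Imaging model and coordinates

Frames hold 8-bit grey levels processed as floats.  Pixel (0, 0) is the
top-left corner, x grows rightward, y grows **downward**; physical
positions are `µm = pixel index × pixel size`, measured at pixel centres.
All tables use micrometres and minutes.  With `skip images = n`, every
(n+1)-th frame is retained and the frame interval Δt is scaled by (n+1),
mimicking longer imaging intervals.

## Frame alignment

Stage-revisiting microscopes misplace consecutive frames by a few pixels.
The pairwise displacement between frames k−1 and k is estimated by an
integer grid search over `[-s, s]²` (default s = 20 px) minimising the
mean absolute grey difference on the overlap region, followed by an
independent 1-D parabola fit through the cost at the optimum and its two
neighbours in each axis.  The refinement offset is clamped to ±0.5 px; if
the integer optimum lies on the search boundary, refinement is skipped
and a warning recorded; a perfect (zero-cost) integer match is returned
unrefined.  Corrections applied to the saved video are the *cumulative*
sums of pairwise estimates, so the whole series shares frame 0's
coordinates and trajectories live in one frame.  Resampling is bilinear
with edge replication; crop margins applied before segmentation discard
the contaminated borders.

Mean absolute difference was kept over mean squared difference: on the
jittered synthetic benchmark the two are equally accurate, and the L1
cost is more robust to bright outliers.  A global shift is only
identifiable relative to *static* image content; in a scene containing
nothing but moving cells the estimator necessarily tracks the mean cell
displacement.  Real plates provide static texture (etching, debris,
collagen); the synthetic registration benchmarks therefore include
static background speckle.

The *velocity sum per cell* — the magnitude of the mean displacement
vector of all matched cells between two frames, divided by Δt — cancels
random cell motion and isolates common (frame-wide) movement.  It is the
run diagnostic for residual misalignment; empty steps yield NaN, never
zero.

## Segmentation

A Gaussian filter with σ = `Gaussian filter radius` (interpreted as the
kernel standard deviation, in µm; configurable) merges intranuclear
speckle into one smooth dark blob per nucleus.  The grey-level limit is
then:

* **manual** (`Segmentation limit = L < 0`): `mean + L·sd` of the whole
  smoothed frame.  This is the classic z-score rule; it adapts to cell
  density because cells contribute to both mean and sd.
* **auto**: the histogram's dominant peak locates the background level
  µ_bg, and the *bright* flank of the peak (unreachable by cells, which
  only darken pixels) gives its half-width; the half-maximum crossing is
  interpolated between bins for stability and converted to σ_bg.  The
  limit is `µ_bg − k·σ_bg` with k = 5 by default: the minimum of ~10⁶
  Gaussian background samples lies ≈4.9σ below the mean, so k = 5 places
  the limit just below the darkest cell-free background pixels.  (k = 3
  sits inside the background's own extreme-value range and produces
  speckle false positives on clean frames.)  σ_bg is floored at half a
  grey level.

Pixels below the limit are labelled with 8-connectivity; components
touching the border are kept, since a cell half outside the analysis
region may enter fully later.

### Cutting touching cells

Regions larger than one `cutting cell diameter` disc are examined for
concave "necks".  The outer boundary is traced with the Moore
neighbourhood (Jacob's stopping criterion); the discrete turning angle at
each boundary point is computed over a ±m window (m = max(3,
0.25·cutting-diameter-in-px)).  Concave local extrema exceeding 35° are
neck candidates; two candidates are paired when their straight-line
separation is under the cutting diameter while their boundary-path
separation exceeds twice the straight line (so a single bulge is never
cut across).  The straight line between a paired set is set to
background.  Up to 3 passes are applied so triplets split.  All
parameters are keyword-configurable.

Separation lines are drawn **2 px thick**: a 1 px background line does
not break 8-connectivity across diagonal steps, so a 1 px cut can leave
the halves connected corner-to-corner and silently fail.

Candidates are gated by equivalent circular diameter (2·√(area·µm²/π),
from area rather than perimeter); centroids are unweighted pixel-centre
means reported in the uncropped frame's µm coordinates.  Note the
*apparent* diameter of a thresholded blob exceeds the size of its dark
core (the contour sits in the intensity tail), so size gates should be
set from the size-distribution plot, not from nominal cell diameters.

## Tracking

Linking is greedy least-displacement: all pairs within `max step =
highest cell velocity × Δt` are sorted ascending by distance (ties:
smaller previous index, then smaller current index) and accepted while
both cells are free.  The most certain (shortest) matches are thus
claimed first.  On 5-cell jittered trials this greedy matching equals the
brute-force minimum-total-distance assignment in well over 95% of cases
(measured in the acceptance suite).

A cell unmatched at frame t but with a candidate within `2 × max step`
among the tracks last seen at t−2 triggers gap repair: an observation at
the arithmetic midpoint is inserted at t−1 and flagged `repaired`.  The
factor 2 is the natural two-frame limit, and the midpoint construction
guarantees each flanking step is within `max step` whenever the
two-frame bound holds.  Tracks end after two consecutive misses;
remaining unmatched cells start new tracks, so every identified cell in
every frame belongs to exactly one track.  Divisions are not detected:
the nearest daughter continues the track, the other starts a new one —
emergent behaviour of the linker, with no lineage recorded.

Optional track smoothing replaces each interior position with the
(¼, ½, ¼)-weighted average of neighbours per iteration, endpoints fixed.
This is the minimal endpoint-preserving low-pass; it strictly decreases
accumulated distance of jittery tracks while leaving the Euclidean
(net) displacement unchanged, damping the spurious velocity of
oversampled slow cells.  Smoothing is applied strictly after tracking.

## Migration metrics

Per track (length ≥ 2): duration = steps × Δt; mean step velocity =
accumulated/duration; Euclidean velocity; directness =
euclidean/accumulated; FMIx, FMIy = signed net displacement per axis /
accumulated distance (accumulated-distance denominator, the convention of
the common chemotaxis analysis tools).  Degenerate denominators
(perfectly static tracks) yield NaN markers that population summaries
skip explicitly — never silent zeros.

The per-video mean velocity is two-stage: step velocities are first
averaged within each frame pair, then averaged over frame pairs.  Where a
"mean velocity per track" is reported, tracks are weighted equally
regardless of length.

Velocity and distance histograms share one machinery: counts are
normalized to sum to 100%, the accumulated curve rises to 100%, the mode
is the vertex of a least-squares quadratic through the peak bin ±2
neighbours (edge peaks fall back to the peak-bin centre with a warning),
the median is interpolated within its bin, and `fraction_above(d)`
interpolates linearly on the accumulated curve.  Distance distributions
for cross-method comparison use 1 µm bins; track sets are matched
one-to-one by first positions within 15 µm (greedy, ascending).  The
far-miss cutoff defaults to 10 µm.

In wound-healing mode the wound midline is the mean y of all track
starting points; FMIy of tracks starting below it is sign-flipped so
positive FMIy means motion into the wound from either edge.

## Synthetic videos and what they do (not) show

The generator emulates the features the pipeline's assumptions rest on:
bright background (default 150), dark Gaussian-profile elliptical nuclei
(depth 60, σ = diameter/4, aspect 0.75–1.0 — the dark core spans roughly
half the nominal cell diameter, as nuclei do), additive pixel noise,
global frame jitter applied after rendering, a static diffuse plate-
etching cross, static collagen-like speckle, and an optional cell-free
wound band with balanced cell placement on both sides and a configurable
drift into the band.  Motion is drift plus isotropic Brownian steps
(per-axis σ, so step lengths are Rayleigh with mean σ√(π/2)), with
excluded volume (cells may not approach closer than 0.9 mean diameters;
real nuclei cannot overlap) and either reflecting borders or an "exit"
mode where cells leave the field of view and their truth ends.
Divisions replace a cell by two daughters offset ±0.6 diameters along a
random axis.  Ground truth stores pre-jitter ("world") positions, so
recovered cumulative alignment shifts compare directly against the
injected jitter list.  A fixed seed reproduces stacks bit-identically.

Deliberately absent: optical physics (defocus, phase-ring halos),
morphology changes, intensity drift over time, cell-shape deformation
during contact, and realistic division morphology (mitotic rounding).
Passing tests therefore demonstrate the *algorithms* are correct under
the stated imaging model; they do not certify performance on any
particular microscope's imagery, where tuning via the size histogram and
the tuning frame remains the user's task.

## Problem sizes and defaults in the verification suite

Synthetic benchmarks run at desk scale: frames of 160–1000 px on a side,
5–150 cells, 2–30 frames; the proliferation benchmark images every 3 h
over 72 h (24 frames) with Brownian σ scaled to that interval; Rayleigh
recovery uses 100 cells × 20 steps = 2000 steps.  Pipeline settings in
fixtures use the manual −1.5 segmentation limit, 3 µm smoothing σ and
size gates bracketing the apparent blob diameter.  The pure-drift
benchmark feeds rendered video through the full pipeline; the
Rayleigh-step benchmark feeds exact detections to the linker only, so it
isolates linker bias from centroid quantisation noise (~0.1–0.2 µm per
observation), which would otherwise contribute a ~1–2% upward bias to
mean step length at σ = 2 µm.

## Known limitations

* No rotational or non-rigid registration; lateral shift only.
* No cytoplasm-outline segmentation; positions are nuclear centroids.
* No division detection or lineage trees; track counts exceed cell
  counts in dense or dividing populations, and long-track metrics
  (accumulated distance, directness, FMI) should be interpreted with
  caution in wound-healing mode where tracks fragment.
* Deeply merged cells (centre separation below the apparent blob
  diameter) present no concave neck and cannot be split by the cutter.
* AVI decoding requires an imageio video backend; multi-page TIFF is the
  dependable interchange format, and overlay videos are written as RGB
  multi-page TIFF (lossless).
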