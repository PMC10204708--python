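# Methods

## Problem and model

The package estimates the distribution of root diameters in a 2D image of
an excavated root system, expressed as *constituent lengths*: the total
centerline length (mm) whose local diameter falls into each class
(1: <2 mm, 2: 2–6 mm, 3: 6–20 mm, 4: >20 mm; half-open intervals
[lo, hi), so exactly 2.0 mm is class 2). Class intervals are lower-
inclusive everywhere because the verbal ranges ("<2", "2–6", …) are
ambiguous at shared borders; one convention had to be fixed.

## Segmentation

Background keying uses the blueness index β = 3B − 2.4G − R (a blue
adaptation of the excess-green-minus-red vegetation index, keeping the
channel weights). β is normalized per frame, β′ = 255·β/max β; if
max β ≤ 0 (no blue background at all, e.g. a single image on black), β′ is
defined as 0 everywhere so the whole frame passes as foreground with a
warning — fail-open keeps non-standard stills usable. Per-frame (rather
than per-video) normalization is the default; a per-video maximum could be
substituted by passing precomputed maps.

Mask fusion is a pointwise AND of foreground, stem, label and blur masks.
The blur mask marks everything within `blur_dilation_px` (default 5) of a
Canny edge (thresholds 50/150 by default); motion-blurred roots lack such
edges and are removed. Still images bypass the blur mask
(`use_blur_mask=False`) since nothing moves. Refinement erodes with a
disk of radius θ (the erosion element is not otherwise constrained; a disk
is isotropic) and removes 8-connected fragments below T_F pixels, matching
the 8-neighborhood convention used for skeletons. The order is erode, then
filter fragments.

## Ridge detection

Gaussian-derivative filtering at scale σ gives the gradient and Hessian of
the smoothed image. The eigenvector of the larger-|eigenvalue| Hessian
eigenvalue defines the normal; bright lines require that eigenvalue to be
negative. A sub-pixel stationary point of the profile along the normal
must fall within ±0.55 px of the pixel center. Salient points with
second-derivative magnitude ≥ u (the analytic center response of a bar of
half-width w and contrast h at scale σ) seed lines; candidates ≥ l extend
them, with hysteresis implemented as connected-component linking
(8-neighborhood) followed by thinning and path tracing; junctions
(>2 neighbors) split lines into simple paths. The default l/u ratio is
0.35, the middle of the commonly recommended 0.25–0.5 band. Kernels are
truncated at 3.5σ.

Width measurement samples the absolute directional derivative along
±normal at 0.5-px steps and takes the distance to the first local maximum
above a floor of half the ideal step-edge response of contrast h,
0.5·h/(√(2π)σ). The floor is what makes over-blurring fail *cleanly*: a
structure much thinner than σ keeps a ridge response but its edges fall
below the floor and the line is dropped — the failure mode the multi-scale
iteration exists to fix. The search length is w + 2.5σ: with σ at its
lower bound w/3 the true edge lies at distance w = 3σ > 2.5σ, so a bare
2.5σ search could never reach the edge of the widest bar in the band.

Two measurement refinements deal with effects absent from the 1D ideal-bar
model:

* **Scale-matched edge localization.** At large σ the smoothing also
  averages *along* the root; on a tapering root this drags the gradient
  extrema of a thick section inward by tens of percent. Points whose
  provisional width is far below what the detection scale warrants are
  re-measured at σ′ ≈ width/12 (quantized to a halving ladder, iterated
  twice); the search reach stays at the detection band (1.1w + 3σ′)
  because the provisional width itself may be badly biased.
* **Medial veto.** Strong shading creates spurious ridge responses on the
  flanks of thick roots ("false positives at the border of thicker roots"),
  complete with plausible-looking edges. A genuine centerline point is a
  local maximum of the foreground distance transform along its normal; a
  flank point is not (the transform keeps rising toward the true axis).
  Points failing this test are marked missing; missing runs up to
  max(7, 1.2·median width) points are bridged by linear interpolation
  along the line (short occlusions, crossings), longer runs drop out, and
  a line with a whole side missing is discarded (every center point needs
  an edge on each side).

## Iterative multi-scale scheme

Plans are geometric w-ladders between the smallest resolvable half-width
(1.5 px) and the configured maximum; 3 steps forward / 4 reverse by
default (three to four iterations suffice in practice; more steps buy
little and cost linearly). σ per step is max(w/3, 1) — the lower bound of
the scale rule, floored for grid stability. The deletion mask dilates each
step's skeletonized centerlines with a disk of diameter γ = 0.9·2w
(implemented exactly via a Euclidean distance transform, which is O(image)
for any radius). In reverse mode each step discards points thinner than
the next step's band (τ_min = 2w_next); forward mode symmetrically defers
points wider than 2.4·2w to later steps — without that cap an early
small-scale step can claim a truncated measurement of a thick root and the
deletion mask then blocks the correct larger-scale measurement.

Postprocessing: dilation by one pixel (closes 1-px gaps), skeletonization,
AND with RS. Widths transfer to skeleton pixels from the nearest raw
centerline pixel within 2 px; farther pixels inherit the map's median
width. Orientation correction tiles the image (32-px tiles, 9 orientation
bins over [0°, 180°)); the dominant bin of a gradient-magnitude-weighted
orientation histogram of the smoothed skeleton, refined by the weighted
circular mean *within* that bin, gives ω_R, folded into [0, π/4], and the
per-pixel length weight τ = 1/cos ω_R ∈ [1, √2]. The in-bin mean matters:
plain 20°-bin centers cannot represent, say, a 30° line, whose correction
factor 1/cos 30° ≈ 1.155 the tests check exactly.

## Classification and aggregation

Each skeleton pixel contributes τ·mm_per_px of length to the class of its
local diameter. Multi-view aggregation over a rotation averages the
per-frame *percentage fractions* (frames with no detections are excluded
and counted); per-class maximum and high-percentile aggregation over the
absolute lengths are available for emphasizing the perspectives that
display a class most fully. Growth dynamics are summarized per week and
class as box-plot statistics with Tukey 1.5·IQR whiskers (linear-
interpolation quartiles).

## Synthetic scenes and what they do (not) show

A root is a disc-swept volume around a gently curved, predominantly
downward planar axis (smoothed random curvature, heading clipped to ±83°
from vertical) with a piecewise-linear radius profile integrated
*analytically* into fine diameter bins (0–1, …, 9–10, 10–15, 15–20, 20–25,
25–30, 30+ mm) that merge losslessly into the four classes. Profiles of
storage types have a narrow proximal neck (45% of the maximum radius for
type IV, 60% for III — cassava storage roots attach by thin woody necks), a
swollen mid-region, and a taper to a ≤1 mm tip, so thick roots cross every
class on the way out. Per-type maximum diameters follow the class bounds
(capped at 45 mm) and lengths 150–400 mm. Scenes are front-lit: brightness
falls from the axis to 75% at the silhouette, giving the round impression
while keeping edge contrast ~2.5× above the default detector contrast
h = 50 (root gray ≈ 125–170 on a zeroed background). Rendering uses a 1-px
signed-distance ramp for anti-aliasing; the blue background is
(R, G, B) = (20, 40, 210).

Systems emulate growth in a thin quasi-2D volume: roots fan from an
anchor region the width of an excavated crown base (±50 mm), fill the fan
evenly with jittered emergence angles, and *steer around* already-placed
roots (overlap-weighted repulsion, ≤0.2 rad per 2-mm step, inactive in the
first 10 mm so bases may adjoin); roots that still end up deeply buried are
regrown at fresh emergence points (best of 10 attempts). The growth series
gives each of 80 roots (40/20/14/6 of destiny types I–IV — storage roots
are few, 3–10 per plant) a piecewise-linear diameter trajectory; type-IV
trajectories are pinned so the first root crosses 20 mm exactly at week 10,
and weekly scenes are stratified 17-root subsets preserving current type
proportions (largest-remainder rounding, per-type deviation ≤ 1 root).

What passing these studies shows: the detector recovers centerlines and
widths across a 4–150 px diameter range, under shading, taper, curvature,
crossings and partial occlusion, with exact bookkeeping of lengths. What
it does not show: robustness to surface texture, dirt, specular highlights,
motion blur, depth-dependent scale changes, or real shading — the
synthetic surfaces are smooth and noiseless, so real-image accuracy will
be lower, particularly for fibrous roots near the resolution limit.

Study resolutions: 0.3 mm/px for the single-root study (type-I roots span
≥ 3 px, the stated feasibility bound for class 1) and 0.6 mm/px for the
system and series studies (class-1 diameters ≤ ~3.3 px, like the video
box, where class 1 is knowingly under-detected; the series regression
therefore uses classes 2–4 and the system study types II–IV). Study sizes
in `scripts/acceptance.py`: 50 single roots per type; 5 systems per type
with 16/10/6 roots for types II/III/IV; 5 subsets × 12 weeks. The pytest
suite runs the same designs at reduced scene counts.

## Numerical and degenerate-input conventions

* mm_per_px is a required calibration input; fixtures use 0.5 mm/px, an
  arbitrary placeholder.
* Grayscale conversion uses Rec.601 luma weights (documented constant;
  the detector's contrast parameter h absorbs the exact choice).
* Empty width maps yield all-zero distributions with NaN fractions and are
  excluded (and counted) by the mean aggregator.
* Both-empty mask comparison defines IoU = 1 with a flag.
* The perspective model defaults to the orthographic limit; the pinhole
  variant needs a focal length, which real setups must calibrate. Its
  rotation average for a horizontal segment, 100·(1 − 2/π) ≈ 36.3%, is the
  model's analytic anchor point.
* Determinism: every stochastic component takes an integer seed through
  `numpy.random.default_rng`; identical seeds give bit-identical scenes
  and identical pipeline outputs.

## Known limitations

* Touching or overlapping parallel roots can merge into one thicker
  detection (counted once, in a higher class); deep basal overlap is
  under-measured. Both effects are visible in the one-type-system study
  as small phantom higher-class lengths and a slope just below 1.
* Fibrous roots below ~2 px diameter are not reliably detected or
  classified; at video-box resolution class 1 is systematically low.
* No root topology: lines are independent paths, not connected root
  systems, and roots are not counted.
* The stem mask is an input; no stem detector is bundled.
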