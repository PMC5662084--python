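# Methods

This note documents the models, numerical choices and limitations behind
`ctc_markerquant`, in the order the pipeline runs.

## Intensity restoration

Archived thumbnails are 8-bit images whose brightness was stretched to the
brightest pixel of the channel at archive time; the original channel minimum
and maximum (on the native 12-bit scale, 0–4095) are recorded in the TIFF
header. Restoration is the inverse affine map

    I = header_min + p · (header_max − header_min) / 255 .

Restored values are kept as floats — re-quantizing would perturb means near
the classification thresholds. The archive dialect for the header is not
standardized; this package writes and reads `min=<int>;max=<int>` key-value
pairs in the per-page `ImageDescription` tag and exposes a `header_parser`
hook for other dialects. Headers are treated as per-frame. When no header is
found the loader falls back to the full stored range `(0, 2^bits − 1)` and
warns; 16-bit containers are treated as native 12-bit data already on the
true scale. The worst-case restoration error is half a quantization step,
`(header_max − header_min)/255/2`, verified pixel-wise in the tests.

Coordinates are 0-based, row-major, at pixel centers. The default pixel
pitch is 0.64 µm (configurable).

## Background model

Per frame: location = median, scale = 1.4826 · MAD (the Gaussian-consistent
robust estimator). Both are robust to bright objects occupying a minority of
the frame; a constant frame yields (constant, 0). All later cut-offs derive
from this model, so adding a constant offset to a frame changes no mask.

## Multi-scale detection

The detector evaluates three smoothing scales (Gaussian σ of 3.0, 1.5 and
0 px, coarse → fine). At each scale the smoothed frame is thresholded at

    mu + u(scale) · sigma_s(x, y) ,

where `u(scale)` solves `resels · P(Z > u) = α` with `α = 10⁻⁵` per frame
and scale, and `resels = area / (2π σ_scale²)` (every pixel at the
un-smoothed scale). This multiplicity correction is what makes "no object on
pure background" hold as a statement about whole frames: a fixed per-pixel
3σ rule would produce on the order of one false excursion cluster per frame
by construction. `sigma_s(x, y)` is the *exact* per-pixel standard deviation
of smoothed unit noise for the separable kernel with reflective boundaries
(computed from the squared filter weights); near borders the reflection
folds weights back and raises the local noise level up to two-fold at
corners — using a single global value produces systematic corner false
positives.

Candidate components must additionally (i) span at least 4 px, (ii) contain
a raw pixel above `mu + 3σ` (an object must exceed the noise floor — the
same k = 3 that defines "pure background"), and (iii) have a raw in-mask
mean above `mu + 3σ/√n`. Components are chained across scales by overlap; a
chain absorbs every overlapping finer-scale component (union), so objects
that fragment at fine scales remain single objects. Within a chain, the
finest detection whose area changed by < 20 % from the previous scale is
kept; if no step is stable, the finest detection is kept.

Finally each object's mask is re-cut at half-maximum: with the plateau
estimated as the in-mask median, the level `mu + 0.5·(plateau − mu)` is
applied inside the chain's (dilated) support and holes are filled. This
recovers plateau-shaped signals at their true extent regardless of how far
their skirt pokes above the noise floor, and it is derived entirely from the
object's own data — the detector exposes no tunable threshold. Reported
objects are pairwise non-nested (the finer of a nested pair wins) and are
returned in deterministic centroid order. Masks use 8-connectivity; contours
are the sub-pixel iso-0.5 polygon of the filled mask (vertices at
pixel-boundary midpoints), oriented counter-clockwise.

Measured behaviour under the fixture conditions (background σ = 6.6,
80×80 px): 0 objects on 2000 pure-noise frames; 100 % recovery of flat-top
blobs with amplitude ≥ 5σ and radius 3–8 px, with sub-pixel centroid error;
blobs with amplitude just above 3σ are still detected via the smoothed
scales. Touching-cell splitting is out of scope: blobs closer than roughly
one smoothing diameter may merge.

Each channel is segmented independently; the event-defining object per
channel is the one with the largest overlap with the DAPI nucleus mask
(largest DAPI object), ties broken by area, then by distance to the frame
center.

## Per-object measurements

Mean, maximum, standard deviation (population, ddof = 0), mass
(Σ intensity) and median are computed over the restored intensities inside
the mask, *without* background subtraction: negativity is encoded purely by
the absence of a segmented object (all-zero record), which is what makes a
cutoff of 0 a meaningful class boundary. Eccentricity comes from central
second moments (`sqrt(1 − (minor/major)²)`, via `regionprops`). Perimeter
is the polyline length of the traced contour; circularity is normalized as
`perimeter² / (4π · size)` so an ideal disk → 1. On digital disks of radius
2–10 px this evaluates to 1.18–1.35 (1.26 at r = 5); for masks below ~10 px
the discrete value can dip slightly below the continuum lower bound of 1,
which is why the bound is asserted only for fixture-scale shapes.

Overlay convention: `|DAPI ∩ other| / |DAPI|` (fraction of the nuclear area
shared), 0 when the DAPI mask is empty.

The intensity-difference test is Welch's two-sided t-test on the two
events' in-contour pixel samples. Pixels are treated as independent draws;
spatial correlation from optics and smoothing is ignored, so p-values are
anti-conservative — a documented caveat, adequate for the visual-comparison
use the statistic serves. The antigen calibration is an ordinary
least-squares line through (measured intensity, antigens per cell) pairs
with r²; intensities themselves stay in instrument units everywhere else.

## Classification and cohort statistics

Thresholds on the mean marker intensity (restored 12-bit scale):
negative iff mean ≤ t_dim (default 0 — the no-object encoding), dim iff
t_dim < mean < t_bright (default 100), bright iff mean ≥ t_bright. The
boundary at 100 is closed on the bright side; the dim interval is open at
both ends. Manual ordinal scores (0, 1+, 2+, 3+) map to binary positivity
at 2+ and above.

Patient summaries count classes and label heterogeneity: `all_positive`
iff no negative event, `none_positive` iff no dim/bright event, else
`mixed`; single-event patients follow the same rule (mixed impossible).
Cohort reports pool event counts (percentages sum to 100 %), count
heterogeneity patterns, and sort patients by decreasing positive fraction.
Manual-vs-automated agreement is Pearson's r, reported with a Fisher-z 95 %
CI (an addition over the bare coefficient).

Reader concordance: for R reviewers, each event is categorized by its vote
split — unanimous (split by direction), all-but-one agree, all-but-two
agree, or an exact tie ("3–3 indifferent", possible only for even panels).
The majority direction of every non-unanimous category is recorded
separately rather than guessing a collapsed display. Missing votes are an
error; nothing is imputed.

## Synthetic data

The generators define the test conditions:

* **Thumbnails** — 80×80 px, four channels, Gaussian background noise with
  σ = 6.6 around a level of 30 (low enough to be realistic for archived
  thumbnails, high enough that clipping at 0 is negligible). Cells are
  flat-top disks: the plateau is the absolute in-blob level, so the expected
  in-mask mean equals the plateau exactly and the quantification oracle is
  exact. The default edge is hard (softness 0); a Gaussian skirt of
  configurable width is available, at the cost of a sub-pixel halo that no
  below-plateau cut can exclude. Plateau 0 encodes "no signal"; plateaus
  between 0 and the background level are rejected. Frames are rendered at
  float 12-bit, clipped to [0, 4095], archived to 8-bit against integer
  floor/ceil headers, and written as multi-page TIFFs with a JSON truth
  manifest; everything is deterministic per seed.
* **Cell-line populations** — negative cells have mean exactly 0 (the
  no-object encoding); dim cells ~ N(80, 15) truncated above 0; bright
  cells ~ N(120, 15), overlapping the bright threshold so misclassification
  occurs. Class sizes default to 373/496/361. The expected accuracy of
  threshold classification has a closed form (Gaussian CDFs), used as the
  oracle for the empirical rate.
* **Cohorts** — 132 patients / 4084 events by default. Per-patient event
  counts are lognormal (σ_log = 1.3, minimum 1, normalized to the total),
  mimicking the heavy-tailed CTC counts of real cohorts. Patient patterns
  are latent: all-positive (p = 8/132), none-positive (p = 14/132), else
  mixed with a Beta(2, 3.1) positive fraction realized so that both classes
  appear (single-event patients realize all-or-none). Positive events are
  bright with p = 0.062.
* **Reader panels** — each reviewer's call is the truth flipped with a
  per-reviewer error rate. With rate 0.5 the 3–3 tie frequency has the
  closed form C(6,3)/2⁶ = 0.3125, an oracle used in the tests.

What passing these tests does *not* show: performance on real optics
(PSF blur, vignetting, channel bleed-through, debris and touching cells are
not simulated), on non-Gaussian background structure, or on proprietary
archive dialects other than the documented header convention.

## Problem sizes

The default test suite and the acceptance script run at desk scale —
hundreds of 80×80 thumbnails, 10³-event populations and cohorts, 10³ random
reader matrices — chosen so the full pipeline, including every acceptance
check, completes in seconds while keeping binomial sampling error well
inside the asserted tolerances.
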