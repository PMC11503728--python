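# Methods

This note documents the models, conventions and numerical choices behind
`herdmotion`, and what the synthetic fixtures do and do not establish
about real pen footage.

## Coordinate and raster conventions

All coordinates are 0-based image pixels: origin at the top-left, x
rightward, y downward, pixel centers at integer positions.  Rasterizing
a contour samples pixel centers under the even-odd rule; a center lying
exactly on an edge counts as inside.  These conventions are not forced
by the mathematics — any consistent choice works — but they match how
segmentation labels are produced (normalized by image width/height) and
they make the moment computation reproducible to the pixel.  The
boundary-inclusive rule is implemented as an explicit second pass over
edge lattice points, so results do not depend on floating-point luck.

## Center-point algorithms

* **Vertex mean** — the average of the raw contour vertices, duplicates
  included.  Vertex density acts as weight: densely annotated or
  repeated stretches (legs, ears) pull the center.  This is deliberate;
  the algorithm exists as the baseline whose failure mode motivates the
  others.
* **Least squares** — iterative gradient descent on
  Σ‖vₖ − c‖².  The minimizer is the vertex mean in closed form, so the
  iteration is not a numerical necessity; it is retained as a distinct,
  comparable algorithm.  The step size contracts the error by exactly
  1/2 per iteration, so `tol` (default 1e-9 px) is reached in ~50
  iterations from any realistic start; exceeding `max_iter` (default
  200) raises an error carrying the last iterate.
* **Signed area** — the shoelace polygon centroid, orientation-
  independent, computed on the deduplicated vertex ring.
* **Spatial moment** — the centroid of the *filled raster mask*,
  (m10/m00, m01/m00).  Internally only the contour's bounding window is
  rasterized and the moments are shifted back, which is exact and keeps
  a 3632 × 1632 frame with ~450-px pigs at ~2 ms per contour.

For a uniform-density shape the signed-area centroid and the continuum
moment centroid coincide; the raster version differs by discretization
only, and converges to the polygon centroid as the shape grows in
pixels (≤ 0.5 px at ≥ 512-px body scale; measured ~0.03 px).  The two
algorithms still react differently to *contour perturbations* at fixed
resolution, which is what separates them on lying pigs.

## Group position and clustering

Per-frame centers are merged by bottom-up agglomerative clustering with
Lance–Williams updates (single/complete/average) or the
within-cluster-variance increase (Ward, the default linkage).  Merges
are deterministic: ties break toward the pair of clusters with the
smallest original point indices.  With the default `n_clusters = 1` the
cluster representative — the arithmetic mean of members — equals the
plain mean of all centers, so clustering contributes nothing beyond
configurability at k = 1; this is asserted in the tests rather than
hidden.  The k > 1 extension averages the per-cluster means with equal
cluster weights.  Alternative clusterers (k-means++, DBSCAN, mean
shift, Gaussian mixture; scikit-learn) are available to the runtime
benchmark harness and to `group_center`; they are comparison baselines,
not the method.  DBSCAN in the harness uses `eps` = a quarter of the
point spread with `min_samples = 1` so every point is assigned and
counts are conserved.

Confidence values do not weight the mean by default; a
`confidence_weighted` option exists.

## Displacement and aggregation

D is the Euclidean move between consecutive group points divided by the
image diagonal, × 100.  It is dimensionless and exactly scale-
invariant (verified to 1e-9 relative over random pairs and scales).
D is *not* divided by the elapsed time: at the fixed 5-minute cadence
the daily sum of raw percentages is the activity measure; a
`d_per_hour` rate column is emitted alongside for unevenly sampled
manifests.

Gap policy: frames with zero detections are retained as gaps.  Under
`skip` (default) the adjacent pairs are excluded and counted as
missing — the conservative choice that never invents movement.  Under
`bridge` the pair spans the gap with the elapsed time accumulated,
which understates path length during the gap.  Missing counts are
always reported.

Calendar assignment: a pair belongs to the day (and hour) of its
destination frame; a pair crossing midnight belongs to the later day.
Hourly bins therefore sum to daily totals exactly (up to float
reassociation).

## Occupancy

The density grid normalizes counts by the fullest bin (a 0–1 heatmap
scale); a probability normalization is available.  The default grid is
64 × 29, approximately square bins at the default 3632 × 1632 frame.
Quadrants follow reading order — A top-left, B top-right, C bottom-
left, D bottom-right — with the half-open rule x ≥ W/2 → right,
y ≥ H/2 → bottom, so boundary points are deterministic and the
quadrant counts equal a 2 × 2 grid exactly.  The convention is printed
into every output header.  Period ratios with a zero denominator are
reported as undefined, never infinity.

## Detection evaluation

Matching is greedy in descending confidence at mask-level IoU (the
rasterization above), with unmatched predictions as false positives and
unmatched truths as false negatives.  Greedy confidence-ordered
matching is the common detection-evaluation convention; Hungarian
assignment would differ only in contrived overlap patterns.  Zero-
denominator conventions: P = 0 when TP+FP = 0, R = 0 when TP+FN = 0,
F1 = 0 when P+R = 0.

## Synthetic scenes

The generator emulates a 3632 × 1632 px overhead view of a pen with 7
pigs sampled every 300 s.  Pig contours are star-shaped radius-
modulated ellipses (aspect 2.5:1, 30–50 vertices, mild low-order radial
noise) in three postures.  The lying posture adds 2–4 narrow leg
spikes on one body side: one vertex pushed 0.9–1.3 × the local radius
outward between two flanking vertices 0.02 rad away.  The spikes are
parametric, not anatomical; their design goal is that the vertex-mean
center is displaced toward the leg side strictly more than the moment
center (each lobe is well under 5% of the body area, so the moment
center barely reacts while the tip vertex drags the mean by ~20 px at a
450-px body).  The default body length of 450 px is a plausible
apparent size for 100–120-day pigs at this resolution; it is a free
parameter.

The latent group trajectory is a two-state (rest/move) Markov walk with
reflective boundaries at a margin that keeps whole contours in frame.
A 24-bin activity schedule (Gaussian bumps at hours 9 and 21 over a low
base) scales both the rest→move hazard and the move step length:
activity peaks mean pigs start moving more often *and* cover more
ground.  Move steps have bounded dithered lengths (5.5% of the diagonal
× the hourly multiplier, ±20%) rather than heavy-tailed draws — an
earlier unbounded-step parameterization let single large steps in
random hours mask the diurnal peaks, and pen reflections truncated
peak-hour steps, washing out the contrast.  With the defaults the
expected daily summed distance is ~700–800% of the diagonal and the two
largest ground-truth hourly bins fall on 9 and 21 in ~95% of seeds.

Herd formation is persistent: while resting, each pig's offset from the
group point, posture, heading and contour are frozen and the herd
follows the latent jitter rigidly; on move frames offsets (Gaussian,
1% of the diagonal by default) and shapes are redrawn.  A resting herd
that independently re-scattered every 5 minutes would add ~0.7% of the
diagonal of spurious displacement per rest pair — over 100% per day of
pure measurement noise — and is also not how resting pigs behave.

What the fixtures do not model: pig-to-pig contact and occlusion,
segmentation failure modes (the optional dropout parameter deletes
detections at random, exercising only the gap policy), camera
distortion, and lighting.  Passing tests therefore validate the
post-detection arithmetic under ideal segmentation, not detector
robustness on real footage.

## Problem sizes

The test suite and the acceptance script use: 1000 random pairs × 4
scales for scale invariance; 50 convex polygons at 512–700 px for the
raster-vs-polygon centroid gap; 100 polygons for the least-squares
identity; 20 seeded lying fixtures; one written 576-frame scene for
daily-total recovery through the full file-based pipeline; and 20
seeded 288-frame scenes for hourly-peak recovery.  These sizes keep a
full run in the low minutes while leaving each check comfortably
powered.

## Known limitations

* The group point of a bimodally split herd (some pigs feeding, some
  resting) is a compromise position; with `n_clusters > 1` the mean of
  cluster means is reported, but interpreting it is up to the analyst.
* D sums measurement noise over many pairs; with real detectors the
  per-frame center noise should be characterized before reading small
  daily differences as biology.
* Percentage-of-diagonal displacement is not metric distance; camera
  calibration is out of scope.
* Timestamps are timezone-naive local time; daylight-saving shifts in
  multi-month manifests are the caller's responsibility.
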