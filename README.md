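# herdmotion

Continuous movement monitoring for group-housed pigs from overhead
instance-segmentation output — without tracking individuals.

Modern pen cameras plus a segmentation network (e.g. a YOLO-style
instance segmenter) give, for every sampled frame, one closed contour
per pig.  Tracking each pig across a whole day is fragile: detections
drop out, bodies touch and identities swap.  `herdmotion` takes the
detector-agnostic route instead: it condenses each frame's contours into
a **single group position** and quantifies the herd's movement and space
use from that one time series.  The intended users are precision-
livestock-farming researchers and engineers who already have per-frame
polygon labels and want robust daily activity and occupancy analytics.

## Method

For every frame with detected contours:

1. **Pig center** — each contour is rasterized (pixel-center sampling,
   even-odd rule) and summarized by its spatial image moments

       m_ji = Σ_{x,y} I(x,y) · x^j · y^i ,
       x̄ = m10 / m00 ,   ȳ = m01 / m00 .

   Because every interior pixel carries equal weight, thin appendages —
   the legs of a lying pig — barely move the center.  Three comparison
   algorithms are included: the vertex mean, an iterative least-squares
   center (analytically identical to the vertex mean), and the
   signed-area (shoelace) polygon centroid.

2. **Group point** — the per-pig centers are merged bottom-up by
   agglomerative clustering (deterministic lowest-index tie-breaking);
   with the default single cluster the group point is exactly the mean
   of the centers.  A benchmark harness compares runtimes against
   k-means++, DBSCAN, mean shift and Gaussian-mixture clustering.

3. **Displacement** — between consecutive group points,

       D = 100 · √((x_i − x_{i−1})² + (y_i − y_{i−1})²) / √(H² + W²) ,

   the Euclidean move as a percentage of the image diagonal, so results
   are identical at any image scale.  Frames without detections are
   gaps; the default policy skips gap-adjacent pairs rather than invent
   movement.

4. **Analytics** — daily summed distance, 24-bin hourly profiles,
   occupancy density grids with marginal histograms, quadrant counts and
   between-period ratios, plus precision/recall/F1 evaluation of any
   upstream detector at mask-level IoU.

A seeded synthetic-scene generator (pig-shaped contours in three
postures, a rest/move latent walk with a twin-peak diurnal schedule)
provides ground truth for every stage.

## Worked example

`examples/02_track_a_day.py` simulates one day of 5-minute frames
(7 pigs, 3632 × 1632 px pen) and runs the full pipeline on the written
label files:

```
2023-05-13: recovered   661.9% of diagonal, ground truth   661.2%  (error 0.10%)
two most active hours: [9, 21] (schedule peaks at 9 and 21)
```

The recovered daily total is the summed group-point displacement; it
matches the latent trajectory's total to a fraction of a percent, and
the two busiest hours land on the schedule's morning and evening
activity peaks.  `examples/01_center_points.py` shows why the moment
center is used:

```
mean coordinate: ( 1185.24,   821.06)  off-center 25.72 px
least squares  : ( 1185.24,   821.06)  off-center 25.72 px
signed area    : ( 1199.15,   801.10)  off-center  1.39 px
spatial moment : ( 1199.16,   801.11)  off-center  1.39 px
```

On a lying pig the vertex-weighted centers sit ~26 px toward the legs;
the area-weighted centers stay on the body.  The remaining examples
cover occupancy analysis, detector scoring and the clustering runtime
benchmark.

## Command line

The same workflow is scriptable from a shell:

```sh
herdmotion simulate --days 2 --seed 42 --out scene/
herdmotion track --manifest scene/manifest.csv --out out/
herdmotion report --artifacts out/
herdmotion eval --pred-dir preds/ --truth-dir truths/ --geom 3632x1632 --iou 0.5 --out ev/
herdmotion bench-cluster --frames points.csv --algos agglomerative,dbscan --reps 30 --out bench.csv
```

Inputs are YOLO-segmentation polygon label files (one text file per
frame; `class x1 y1 x2 y2 ...` normalized, optional trailing
confidence) plus a manifest CSV (`frame_id,timestamp,label_path,width,
height`).  All outputs are CSV; reports are PNG figures.

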