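"""Score a noisy detector against ground-truth contours.

Takes one simulated frame's pig contours as the truth, builds imperfect
"predictions" (jittered copies, one missed pig, one stray detection),
and reports IoU-matched precision, recall and F1.
"""

import numpy as np

from herdmotion import (
    FrameGeometry,
    Point2D,
    Polygon,
    detection_metrics,
    match_detections,
)
from herdmotion.synthetic import PenConfig, generate_pig_polygon, simulate_group_walk

truth_scene = simulate_group_walk(PenConfig(n_frames=1, seed=5))
truths = truth_scene.polygons[0]
geom = truth_scene.config.geometry
rng = np.random.default_rng(1)

preds = []
for poly in truths[:-1]:  # miss the last pig
    jitter = rng.normal(0, 6, poly.vertices.shape)
    preds.append((Polygon(poly.vertices + jitter), float(rng.uniform(0.85, 0.99))))
stray = generate_pig_polygon(Point2D(300, 300), "standing", 450, 1.0, rng)
preds.append((stray, 0.40))

m = match_detections(preds, truths, iou_threshold=0.5, geom=geom)
p, r, f1 = detection_metrics(m.tp, m.fp, m.fn)
print(f"TP={m.tp} FP={m.fp} FN={m.fn}")
print(f"precision={p:.3f} recall={r:.3f} F1={f1:.3f}")
for pred_i, truth_i, iou in m.pairs:
    print(f"  prediction {pred_i} matched truth {truth_i} at IoU {iou:.3f}")

# With 6 of 7 pigs found plus one stray box: P = 6/7, R = 6/7.
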