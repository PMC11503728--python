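"""Runtime benchmark of clustering algorithms on per-frame pig centers.

Each frame contributes 7 center points; every algorithm condenses them
to clusters, and the harness reports the median per-frame runtime and
the averaged total.  No winner is asserted — runtimes are hardware-
dependent — but agglomerative clustering is typically among the fastest
at this problem size.
"""

import numpy as np

from herdmotion import benchmark_clusterers

rng = np.random.default_rng(0)
frames = [rng.uniform(0, [3632, 1632], (7, 2)) for _ in range(50)]

table = benchmark_clusterers(
    frames,
    algorithms=["agglomerative", "kmeans++", "dbscan", "meanshift", "gmm"],
    repetitions=5,
)
totals = table[table["frame"] == "total"].sort_values("runtime_s")
print("total runtime over 50 frames (mean of 5 repetitions):")
for _, row in totals.iterrows():
    print(f"  {row['algorithm']:>13}: {row['runtime_s'] * 1e3:8.2f} ms")
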