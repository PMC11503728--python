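"""Simulate a day of pen footage and run the full monitoring pipeline.

Generates a synthetic scene (label files + manifest) with a known latent
group trajectory, runs ingest -> centers -> group point -> displacement
-> daily/hourly analytics, and compares the recovered daily movement
total against the ground truth.
"""

import tempfile
from pathlib import Path

from herdmotion import PipelineConfig, aggregate_daily, hourly_profile, run_pipeline
from herdmotion.synthetic import (
    PenConfig,
    default_activity_schedule,
    simulate_group_walk,
    write_scene,
)

config = PenConfig(n_frames=288, seed=7)  # one day at 5-minute cadence
truth = simulate_group_walk(config, activity_schedule=default_activity_schedule())

with tempfile.TemporaryDirectory() as tmp:
    scene = Path(tmp) / "scene"
    write_scene(truth, scene)
    result = run_pipeline(
        PipelineConfig(manifest=scene / "manifest.csv", out_dir=Path(tmp) / "out")
    )

    for day in aggregate_daily(result.series):
        expected = truth.daily_totals()[day.day]
        print(
            f"{day.day}: recovered {day.total_d:7.1f}% of diagonal, "
            f"ground truth {expected:7.1f}%  "
            f"(error {100 * abs(day.total_d - expected) / expected:.2f}%)"
        )
    profile = hourly_profile(result.series)
    top = profile.nlargest(2, "total_d")["hour"].tolist()
    print(f"two most active hours: {sorted(top)} (schedule peaks at 9 and 21)")

# The daily total is the summed Euclidean displacement of the herd's
# single cluster point between 5-minute frames, as a percentage of the
# image diagonal; it typically recovers the latent total within ~1%.
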