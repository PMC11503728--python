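"""Where does the herd spend its time?  Density grid and quadrant ratios.

Bins simulated group positions into an occupancy grid (density scaled to
the fullest bin, like a heatmap color bar from 0 to 1) and counts visits
to the four pen quadrants in two halves of the observation period.
"""

from herdmotion import Point2D, density_grid, period_compare, quadrant_counts
from herdmotion.occupancy import REGION_CONVENTION
from herdmotion.synthetic import PenConfig, simulate_group_walk

truth = simulate_group_walk(PenConfig(n_frames=576, seed=3))
geom = truth.config.geometry
points = [Point2D(float(x), float(y)) for x, y in truth.latent]

grid = density_grid(points, geom, nx=8, ny=4)
print("occupancy density (rows = y bins, top to bottom):")
for row in grid.density:
    print("  " + " ".join(f"{v:.2f}" for v in row))

half = len(points) // 2
rc1 = quadrant_counts(points[:half], geom, period="first half")
rc2 = quadrant_counts(points[half:], geom, period="second half")
print(f"\nregion convention: {REGION_CONVENTION}")
print(period_compare(rc1, rc2).to_string(index=False))

# The ratio column says how much more often the herd used each quadrant
# in the first period than the second; NaN marks an empty denominator.
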