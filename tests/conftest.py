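import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from herdmotion import Polygon
from herdmotion.movement import FrameGeometry
from herdmotion.synthetic import PenConfig, simulate_group_walk


@pytest.fixture
def unit_square() -> Polygon:
    return Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def l_shape() -> Polygon:
    return Polygon([(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)])


@pytest.fixture
def pen_geom() -> FrameGeometry:
    return FrameGeometry(3632, 1632)


@pytest.fixture(scope="session")
def tiny_scene_config() -> PenConfig:
    """A small pen that keeps unit tests fast; same model, smaller numbers."""
    return PenConfig(
        width=640,
        height=360,
        n_pigs=3,
        body_length_px=60.0,
        interval_s=300.0,
        n_frames=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_scene(tiny_scene_config):
    return simulate_group_walk(tiny_scene_config)


def random_star_polygon(rng: np.random.Generator, scale: float = 100.0, n: int = 24) -> Polygon:
    """Random non-self-intersecting polygon (radius function of angle)."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    radius = scale * rng.uniform(0.4, 1.0, n)
    center = rng.uniform(2 * scale, 4 * scale, 2)
    return Polygon(
        np.column_stack(
            [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
        )
    )


def random_convex_polygon(rng: np.random.Generator, scale: float = 100.0, n: int = 20) -> Polygon:
    """Random convex polygon as a convex hull of gaussian points."""
    from scipy.spatial import ConvexHull

    pts = rng.normal(0, scale / 2.5, (n, 2))
    hull = ConvexHull(pts)
    verts = pts[hull.vertices]
    span = verts.max(axis=0) - verts.min(axis=0)
    verts = verts * (scale / span.max())
    return Polygon(verts - verts.min(axis=0) + rng.uniform(0, scale / 2, 2))
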