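import numpy as np
import pytest

from finid.config import PipelineConfig
from finid.curves import PlanarCurve, resample_curve
from finid.synthetic import make_dataset, make_population


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def circle64():
    t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    return PlanarCurve(np.column_stack([10 * np.cos(t), 10 * np.sin(t)]),
                       closed=True)


@pytest.fixture()
def square128():
    corners = [(0, 0), (10, 0), (10, 10), (0, 10)]
    pts = []
    for k in range(4):
        a = np.array(corners[k], float)
        b = np.array(corners[(k + 1) % 4], float)
        for u in np.linspace(0, 1, 32, endpoint=False):
            pts.append(a + (b - a) * u)
    return resample_curve(PlanarCurve(np.array(pts), closed=True), 128)


@pytest.fixture()
def wiggly_open():
    """An open curve with curvature everywhere (no straight subsections)."""
    u = np.linspace(0, 4 * np.pi, 300)
    return PlanarCurve(np.column_stack([u * 8.0, 20 * np.sin(u) + 5 *
                                        np.sin(3.1 * u)]), closed=False)


@pytest.fixture(scope="session")
def small_population():
    return make_population(6, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """6 individuals x 3 sightings, easy preset, contours only."""
    return make_dataset(6, 3, preset="easy", seed=11, render_images=False)


@pytest.fixture(scope="session")
def small_config():
    return PipelineConfig(fin_keypoints=10, seed=11)


def star_curve(n_points: int = 9, n_samples: int = 360,
               r_outer: float = 40.0, r_inner: float = 22.0,
               phase: float = 0.0) -> PlanarCurve:
    """A star polygon: plenty of well-separated boundary corners."""
    corners = []
    for k in range(2 * n_points):
        r = r_outer if k % 2 == 0 else r_inner
        a = phase + np.pi * k / n_points
        corners.append([50 + r * np.cos(a), 50 + r * np.sin(a)])
    corners = np.array(corners)
    pts = []
    per_seg = n_samples // (2 * n_points)
    for k in range(2 * n_points):
        a, b = corners[k], corners[(k + 1) % (2 * n_points)]
        for u in np.linspace(0, 1, per_seg, endpoint=False):
            pts.append(a + (b - a) * u)
    return PlanarCurve(np.array(pts), closed=True)
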