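import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from shapely.geometry import LineString, Point, Polygon

from littoral.geometry import LakeGeometry
from littoral.synthetic import SyntheticLakeSpec, make_lake

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def circle_ring(radius: float, n: int = 720, depth_offset: float = 0.0) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t)])


@pytest.fixture(scope="session")
def circle_lake():
    """Circle R=500 m, single 5 m isobath at R=250 m (hand-checkable interpolation)."""
    shore = Polygon(circle_ring(500.0))
    iso = circle_ring(250.0)
    geom = LakeGeometry(
        shoreline=shore,
        isobaths=[(5.0, LineString(np.vstack([iso, iso[:1]])))],
        z_max=10.0,
        lake_id="CIRC",
    )
    return geom


@pytest.fixture(scope="session")
def conic_lake():
    """Conic circle lake R=500 m, 10 m deep: slope 1.146 deg everywhere off-center."""
    spec = SyntheticLakeSpec(
        lake_id="CONE", radius_m=500.0, max_depth_m=10.0, profile="conic",
        n_transects=8, cell_size=2.0, seed=11,
    )
    return make_lake(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
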