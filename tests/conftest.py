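import numpy as np
import pytest

from revaccess.config import CovariateSpec, SyntheticCityConfig
from revaccess.synthetic import generate_city
from revaccess.types import Edge, FoodOutlet, StreetNetwork


@pytest.fixture(scope="session")
def small_city_cfg() -> SyntheticCityConfig:
    """A compact city: fast to generate and analyse, still structurally full."""
    return SyntheticCityConfig(
        seed=42, extent=(4000.0, 4000.0), grid_spacing=400.0,
        n_restaurants=25, n_grocers=6, n_zones=36,
        n_transit_routes=3, stop_spacing=800.0)


@pytest.fixture(scope="session")
def small_city(small_city_cfg):
    return generate_city(small_city_cfg)


@pytest.fixture()
def line_network() -> StreetNetwork:
    """A straight 2000 m road split into two 1000 m edges."""
    return StreetNetwork({0: (0, 0), 1: (1000, 0), 2: (2000, 0)},
                         {0: Edge(0, 1, 1000), 1: Edge(1, 2, 1000)})


@pytest.fixture()
def grid_network() -> StreetNetwork:
    """Exact 10x10 grid, 100 m spacing, no jitter."""
    nodes = {i * 10 + j: (i * 100.0, j * 100.0) for i in range(10) for j in range(10)}
    edges = {}
    eid = 0
    for i in range(10):
        for j in range(10):
            a = i * 10 + j
            if i + 1 < 10:
                edges[eid] = Edge(a, (i + 1) * 10 + j, 100.0)
                eid += 1
            if j + 1 < 10:
                edges[eid] = Edge(a, i * 10 + j + 1, 100.0)
                eid += 1
    return StreetNetwork(nodes, edges)


def make_outlet(oid=0, x=0.0, y=0.0, efo=1, revenue=1e6, sqft=1000.0) -> FoodOutlet:
    return FoodOutlet(id=oid, x=x, y=y, efo_type=efo, revenue_usd=revenue,
                      floor_area_sqft=sqft)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
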