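"""Revealed Accessibility Index: weights, network distance matrix oracle,
hand-evaluated index values, scale law, and brute-force equivalence."""

import math

import networkx as nx
import numpy as np
import pytest
from shapely.geometry import Point

from revaccess.config import RAIConfig
from revaccess.rai import (DistanceMatrix, compute_rai, network_distance_matrix,
                           outlet_weight, outlet_weights, sqrt_transform)
from revaccess.service_areas import walk_service_area
from revaccess.types import FoodOutlet

from conftest import make_outlet


def _outlets(revs, sqfts):
    return [make_outlet(oid=i, x=float(i), y=0.0, revenue=r, sqft=s)
            for i, (r, s) in enumerate(zip(revs, sqfts))]


def test_weight_hand_example():
    o = _outlets([2e6, 1e6], [1000, 1000])
    np.testing.assert_allclose(outlet_weights(o), [1.0, 0.5])


def test_max_revenue_density_outlet_gets_weight_one():
    o = _outlets([1e6, 3e6, 2e6], [500, 1000, 4000])
    w = outlet_weights(o)
    assert w[np.argmax([r / s for r, s in [(1e6, 500), (3e6, 1000), (2e6, 4000)]])] == 1.0
    assert np.all((w > 0) & (w <= 1))


def test_identical_outlets_all_weight_one():
    o = _outlets([1e6] * 4, [1000] * 4)
    np.testing.assert_allclose(outlet_weights(o), np.ones(4))


def test_weight_no_normalization():
    o = _outlets([2e6, 1e6], [1000, 2000])
    np.testing.assert_allclose(outlet_weights(o, "none"), [2000.0, 500.0])


def test_rai_two_competitor_hand_example():
    """Two unit-weight competitors at 1 km and 2 km:
    (1/2)(1*1^-2 + 1*2^-2) = 0.625, sqrt = 0.79057."""
    o = _outlets([1e6] * 3, [1000] * 3)
    d = DistanceMatrix([0, 1, 2], np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float))
    cfg = RAIConfig(competitor_scope="all_city")
    rai = compute_rai(0, o, d, None, cfg)
    assert rai == pytest.approx(0.625, abs=1e-12)
    assert sqrt_transform(rai) == pytest.approx(0.7905694150420949, abs=1e-9)


def test_rai_inverse_square_scale_law():
    o = _outlets([1e6, 2e6, 5e5, 8e5], [1000, 800, 1200, 900])
    base = np.array([[0, 1, 2, 3], [1, 0, 1.5, 2.5], [2, 1.5, 0, 1.2], [3, 2.5, 1.2, 0]])
    cfg = RAIConfig(competitor_scope="all_city")
    for j in range(4):
        r1 = compute_rai(j, o, DistanceMatrix(list(range(4)), base), None, cfg)
        r2 = compute_rai(j, o, DistanceMatrix(list(range(4)), 2 * base), None, cfg)
        assert r2 == pytest.approx(r1 / 4.0, rel=1e-12)


def test_rai_distance_floor_caps_colocated():
    o = _outlets([1e6, 1e6], [1000, 1000])
    d = DistanceMatrix([0, 1], np.array([[0.0, 0.0], [0.0, 0.0]]))
    cfg = RAIConfig(competitor_scope="all_city", min_distance_km=0.05)
    assert compute_rai(0, o, d, None, cfg) == pytest.approx(0.05 ** -2)


def test_no_competitors_in_scope_gives_zero(small_city):
    o = small_city.outlets[0]
    others = [x for x in small_city.outlets]
    d = network_distance_matrix(others, small_city.network)
    # a service area nowhere near any other outlet: shrink the walk polygon to a point-ish buffer
    sa = walk_service_area(o, small_city.network)
    sa.polygon = Point(-5000.0, -5000.0).buffer(1.0)
    assert compute_rai(o.id, others, d, sa) == 0.0


def test_sqrt_transform_domain():
    assert sqrt_transform(0.0) == 0.0
    assert sqrt_transform(1.0) == 1.0
    with pytest.raises(ValueError):
        sqrt_transform(-0.1)


def test_distance_matrix_properties(small_city):
    d = network_distance_matrix(small_city.outlets, small_city.network)
    n = len(small_city.outlets)
    assert np.allclose(np.diag(d.d), 0.0)
    assert np.allclose(d.d, d.d.T, atol=1e-9)
    finite = d.d[np.isfinite(d.d)]
    assert np.all(finite >= 0)
    # triangle inequality for a shortest-path metric
    for _ in range(50):
        i, j, k = np.random.default_rng(_).integers(0, n, 3)
        assert d.d[i, j] <= d.d[i, k] + d.d[k, j] + 1e-9


def test_distance_matrix_matches_networkx_oracle(small_city):
    d = network_distance_matrix(small_city.outlets, small_city.network)
    g = small_city.network.to_networkx()
    nodes = sorted(small_city.network.nodes)
    xy = np.array([small_city.network.nodes[n] for n in nodes])
    for i, oi in enumerate(small_city.outlets[:10]):
        src = nodes[int(np.argmin(((xy - [oi.x, oi.y]) ** 2).sum(axis=1)))]
        lengths = nx.single_source_dijkstra_path_length(g, src, weight="length_m")
        for j, oj in enumerate(small_city.outlets[:10]):
            dst = nodes[int(np.argmin(((xy - [oj.x, oj.y]) ** 2).sum(axis=1)))]
            assert d.d[i, j] == pytest.approx(lengths[dst] / 1000.0, abs=1e-9)


def test_rai_matches_brute_force_on_city(small_city):
    """compute_rai equals an explicit double loop over outlets with scope
    filtering, to 1e-12 relative."""
    city = small_city
    d = network_distance_matrix(city.outlets, city.network)
    cfg = RAIConfig()
    w = outlet_weights(city.outlets)
    for o in city.outlets:
        sa = walk_service_area(o, city.network)
        got = compute_rai(o.id, city.outlets, d, sa, cfg)
        ji = d.ids.index(o.id)
        comps = [k for k, other in enumerate(city.outlets)
                 if other.id != o.id and sa.polygon.covers(Point(other.x, other.y))]
        if not comps:
            assert got == 0.0
            continue
        s = 0.0
        for k in comps:
            c = max(d.d[ji, k], cfg.min_distance_km)
            if math.isfinite(c):
                s += w[k] * c ** -2
        expected = s / len(comps)
        assert got == pytest.approx(expected, rel=1e-12)
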