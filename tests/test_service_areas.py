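"""Service-area delineation: shortest-path oracle equivalence, pro-rata
edge truncation, transit composition, polygonization geometry."""

import math

import networkx as nx
import numpy as np
import pytest
from shapely.geometry import Point

from revaccess.service_areas import (BIKE_DIST_KM, TRANSIT_ALONG_KM, TRANSIT_STOP_KM,
                                     WALK_DIST_KM, SnapError, bike_service_area,
                                     network_reach, polygonize_reach, snap_to_network,
                                     transit_service_area, walk_service_area)
from revaccess.synthetic import generate_city
from revaccess.types import Edge, FoodOutlet, StreetNetwork, TransitSystem

from conftest import make_outlet


def test_mode_distance_defaults():
    # the three active-travel budgets: walking, bicycling, transit ride + stop egress
    assert WALK_DIST_KM == 0.40
    assert BIKE_DIST_KM == 8.04
    assert (TRANSIT_ALONG_KM, TRANSIT_STOP_KM) == (5.36, 0.40)
    import inspect
    assert inspect.signature(walk_service_area).parameters["max_dist_km"].default == 0.40
    assert inspect.signature(bike_service_area).parameters["max_dist_km"].default == 8.04


def test_straight_road_midpoint_reaches_800m(line_network):
    o = make_outlet(x=1000, y=0)
    sa = walk_service_area(o, line_network)
    total = sum(f * line_network.edges[e].length_m for e, f in sa.reached_edges.items())
    assert total == pytest.approx(800.0)


def test_reached_distances_match_dijkstra_oracle(grid_network):
    """Node distances from the reach computation equal exhaustive Dijkstra
    exactly on a 10x10 grid."""
    eid, off, _ = snap_to_network((450.0, 430.0), grid_network)
    _, dist = network_reach(grid_network, eid, off, budget_m=1e9)
    e = grid_network.edges[eid]
    g = grid_network.to_networkx()
    ga = nx.single_source_dijkstra_path_length(g, e.node_a, weight="length_m")
    gb = nx.single_source_dijkstra_path_length(g, e.node_b, weight="length_m")
    for node in grid_network.nodes:
        oracle = min(off + ga[node], (e.length_m - off) + gb[node])
        assert dist[node] == pytest.approx(oracle, abs=1e-9)


def test_reach_set_matches_oracle_at_budget(grid_network):
    budget = 350.0
    eid, off, _ = snap_to_network((400.0, 400.0), grid_network)  # exactly node 44
    _, dist = network_reach(grid_network, eid, off, budget_m=budget)
    g = grid_network.to_networkx()
    oracle = nx.single_source_dijkstra_path_length(g, 44, weight="length_m", cutoff=budget)
    reached = {n for n, d in dist.items() if n >= 0 and d <= budget}
    assert reached == set(oracle)


def test_star_graph_truncation():
    nodes = {0: (0, 0), 1: (5000, 0), 2: (0, 8000), 3: (-9000, 0)}
    edges = {0: Edge(0, 1, 5000), 1: Edge(0, 2, 8000), 2: Edge(0, 3, 9000)}
    star = StreetNetwork(nodes, edges)
    sa = bike_service_area(make_outlet(x=0, y=0), star)
    assert sa.reached_edges[0] == pytest.approx(1.0)
    assert sa.reached_edges[1] == pytest.approx(1.0)
    assert sa.reached_edges[2] == pytest.approx(8040.0 / 9000.0)


def test_walk_nested_in_bike(small_city):
    for o in small_city.outlets[:8]:
        walk = walk_service_area(o, small_city.network)
        bike = bike_service_area(o, small_city.network)
        assert set(walk.reached_edges) <= set(bike.reached_edges)
        for e, f in walk.reached_edges.items():
            assert bike.reached_edges[e] >= f - 1e-9


def test_walk_nested_in_transit(small_city):
    o = small_city.outlets[0]
    walk = walk_service_area(o, small_city.network)
    tr = transit_service_area(o, small_city.network, small_city.transit)
    assert set(walk.reached_edges) <= set(tr.reached_edges)
    assert tr.area_km2 >= walk.area_km2 - 1e-12


def test_transit_without_reachable_stop_equals_walk(line_network):
    # a single stop far beyond the 0.40 km walk reach
    ts = TransitSystem(routes=[[0, 1]], cumdist_m=[[0.0, 1000.0]], stops={0: 0, 1: 2})
    far = StreetNetwork({0: (0, 0), 1: (1000, 0), 2: (2000, 0), 3: (3000, 0)},
                        {0: Edge(0, 1, 1000), 1: Edge(1, 2, 1000), 2: Edge(2, 3, 1000)})
    o = make_outlet(x=3000, y=0)
    walk = walk_service_area(o, far)
    tr = transit_service_area(o, far, ts)
    assert tr.reached_edges.keys() == walk.reached_edges.keys()
    for e in walk.reached_edges:
        assert tr.reached_edges[e] == pytest.approx(walk.reached_edges[e])


def test_transit_straight_route_hand_construction():
    """Outlet at stop 0 of a straight route with 1 km stop spacing: stops
    0-5 are within 5.36 km; coverage is 400 m at the end stop plus 800 m
    around each interior stop = 4400 m."""
    nodes = {i: (i * 1000.0, 0.0) for i in range(11)}
    edges = {i: Edge(i, i + 1, 1000.0) for i in range(10)}
    net = StreetNetwork(nodes, edges)
    ts = TransitSystem(routes=[list(range(11))],
                       cumdist_m=[[i * 1000.0 for i in range(11)]],
                       stops={i: i for i in range(11)})
    sa = transit_service_area(make_outlet(x=0, y=0), net, ts)
    total = sum(f * 1000.0 for f in sa.reached_edges.values())
    assert total == pytest.approx(4400.0)


def test_snap_beyond_tolerance_names_outlet():
    net = StreetNetwork({0: (0, 0), 1: (1000, 0)}, {0: Edge(0, 1, 1000)})
    with pytest.raises(SnapError, match="outlet 99"):
        walk_service_area(make_outlet(oid=99, x=500, y=500), net)


def test_polygonize_rectangle_plus_endcaps():
    net = StreetNetwork({0: (0, 0), 1: (1000, 0)}, {0: Edge(0, 1, 1000)})
    _, area = polygonize_reach({0: 1.0}, net, buffer_m=50)
    expected = (1000 * 100 + math.pi * 50 ** 2) / 1e6
    assert area == pytest.approx(expected, rel=1e-3)


def test_polygonize_area_monotone_in_buffer():
    net = StreetNetwork({0: (0, 0), 1: (1000, 0)}, {0: Edge(0, 1, 1000)})
    areas = [polygonize_reach({0: 1.0}, net, buffer_m=b)[1] for b in (10, 25, 50, 100)]
    assert all(a < b for a, b in zip(areas, areas[1:]))


def test_polygonize_empty_reach_errors(line_network):
    with pytest.raises(ValueError):
        polygonize_reach({}, line_network)


def test_area_consistent_with_polygon(small_city):
    sa = walk_service_area(small_city.outlets[0], small_city.network)
    assert sa.area_km2 == pytest.approx(sa.polygon.area / 1e6, rel=1e-9)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_polygon_contains_reached_midpoints(seed):
    from revaccess.config import SyntheticCityConfig
    city = generate_city(SyntheticCityConfig(
        seed=seed, extent=(2000.0, 2000.0), grid_spacing=400.0,
        n_restaurants=4, n_grocers=1, n_zones=4, n_transit_routes=1))
    for o in city.outlets:
        sa = walk_service_area(o, city.network)
        for eid, f in sa.reached_edges.items():
            if f >= 0.999:
                mid = city.network.edge_geometry(eid).interpolate(0.5, normalized=True)
                assert sa.polygon.buffer(1e-6).contains(mid)


def test_mirror_symmetry():
    """Two outlets at mirror-image positions of a symmetric path network
    produce congruent (equal-area, equal-reach) service areas."""
    nodes = {i: (i * 200.0, 0.0) for i in range(11)}
    edges = {i: Edge(i, i + 1, 200.0) for i in range(10)}
    net = StreetNetwork(nodes, edges)
    left = walk_service_area(make_outlet(oid=0, x=400, y=0), net)
    right = walk_service_area(make_outlet(oid=1, x=1600, y=0), net)
    assert left.area_km2 == pytest.approx(right.area_km2, rel=1e-9)
    assert sorted(left.reached_edges.values()) == pytest.approx(
        sorted(right.reached_edges.values()))
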