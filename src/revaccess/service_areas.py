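"""Mode-specific network service areas around food outlets.

A service area is the set of network locations reachable from an outlet
within a mode's distance budget, measured along the network (never
Euclidean):

- walk: 0.40 km on the pedestrian network;
- bike: 8.04 km on the full network;
- transit: the walk area, plus — for every stop within 0.40 km walking of
  the outlet — all stops within 5.36 km cumulative along-route distance,
  each contributing its own 0.40 km walking reach (walk -> ride -> walk;
  no transfers between routes).

Edges are truncated pro rata by the remaining budget, so long edges are
reached partially rather than all-or-nothing. Outlets snap to the nearest
edge by perpendicular projection (100 m tolerance by default); reach is
computed by Dijkstra from the snap point with the source edge split at it.
"""

from __future__ import annotations

import heapq
import math

from shapely import union_all
from shapely.geometry import LineString, Point
from shapely.ops import substring

from .types import CityBundle, FoodOutlet, ServiceArea, StreetNetwork, TransitSystem

__all__ = [
    "walk_service_area",
    "bike_service_area",
    "transit_service_area",
    "polygonize_reach",
    "snap_to_network",
    "network_reach",
    "city_service_areas",
    "WALK_DIST_KM",
    "BIKE_DIST_KM",
    "TRANSIT_ALONG_KM",
    "TRANSIT_STOP_KM",
]

WALK_DIST_KM = 0.40
BIKE_DIST_KM = 8.04
TRANSIT_ALONG_KM = 5.36
TRANSIT_STOP_KM = 0.40

SNAP_TOLERANCE_M = 100.0
DEFAULT_BUFFER_M = 50.0

Intervals = list[tuple[float, float]]


class SnapError(ValueError):
    """Raised when an outlet lies beyond the snap tolerance of the network."""


def snap_to_network(point: tuple[float, float], network: StreetNetwork,
                    pedestrian_only: bool = False,
                    tolerance_m: float = SNAP_TOLERANCE_M) -> tuple[int, float, float]:
    """Perpendicular-project ``point`` onto the nearest eligible edge.

    Returns ``(edge_id, offset_m, snap_dist_m)`` where ``offset_m`` is the
    along-edge distance of the snap point from ``node_a``.
    """
    p = Point(point)
    best = None
    for eid, e in network.edges.items():
        if pedestrian_only and not e.pedestrian:
            continue
        line = network.edge_geometry(eid)
        d = line.distance(p)
        if best is None or d < best[2]:
            best = (eid, line.project(p), d)
    if best is None or best[2] > tolerance_m:
        raise SnapError(
            f"point {point} lies beyond the {tolerance_m} m snap tolerance of the network")
    return best


def _adjacency(network: StreetNetwork, pedestrian_only: bool) -> dict[int, list[tuple[int, float, int]]]:
    adj: dict[int, list[tuple[int, float, int]]] = {nid: [] for nid in network.nodes}
    for eid, e in network.edges.items():
        if pedestrian_only and not e.pedestrian:
            continue
        adj[e.node_a].append((e.node_b, e.length_m, eid))
        adj[e.node_b].append((e.node_a, e.length_m, eid))
    return adj


def _dijkstra(adj: dict, sources: dict, cutoff: float) -> dict[int, float]:
    """Single/multi-source Dijkstra with a distance cutoff."""
    dist: dict[int, float] = {}
    heap = [(d0, s) for s, d0 in sources.items() if d0 <= cutoff]
    heapq.heapify(heap)
    while heap:
        d, u = heapq.heappop(heap)
        if u in dist:
            continue
        dist[u] = d
        for v, w, _eid in adj.get(u, ()):
            nd = d + w
            if nd <= cutoff and v not in dist:
                heapq.heappush(heap, (nd, v))
    return dist


def _merge(intervals: Intervals) -> Intervals:
    out: Intervals = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1e-9:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return [(s, e) for s, e in out if e - s > 1e-9]


def network_reach(network: StreetNetwork, edge_id: int, offset_m: float,
                  budget_m: float, pedestrian_only: bool = False,
                  extra_sources: dict[int, float] | None = None,
                  ) -> tuple[dict[int, Intervals], dict[int, float]]:
    """Reached along-edge intervals from a point on an edge.

    The source edge is split at the snap point (a virtual node), after which
    every edge's coverage adjoins its endpoints and the pro-rata truncation
    ``reached = (budget - dist_to_endpoint)`` is exact.

    Returns ``(intervals_by_edge, node_distances)``; ``extra_sources`` lets
    transit composition start additional reaches at stop nodes.
    """
    adj = _adjacency(network, pedestrian_only)
    e0 = network.edges[edge_id]
    t = offset_m
    L0 = e0.length_m
    SRC = -1  # virtual snap node
    sources = {SRC: 0.0}
    if extra_sources:
        sources.update(extra_sources)
    adj[SRC] = []
    if t > 1e-9:
        adj[SRC].append((e0.node_a, t, edge_id))
        adj[e0.node_a].append((SRC, t, edge_id))
    else:
        sources[e0.node_a] = min(sources.get(e0.node_a, math.inf), 0.0)
    if L0 - t > 1e-9:
        adj[SRC].append((e0.node_b, L0 - t, edge_id))
        adj[e0.node_b].append((SRC, L0 - t, edge_id))
    else:
        sources[e0.node_b] = min(sources.get(e0.node_b, math.inf), 0.0)

    dist = _dijkstra(adj, sources, cutoff=budget_m)
    intervals: dict[int, Intervals] = {}
    for eid, e in network.edges.items():
        if pedestrian_only and not e.pedestrian:
            continue
        L = e.length_m
        pieces: Intervals = []
        da, db = dist.get(e.node_a), dist.get(e.node_b)
        if eid == edge_id:
            dsrc = dist.get(SRC)
            if dsrc is not None:  # direct coverage around the snap point
                r = budget_m - dsrc
                pieces.append((max(0.0, t - r), min(L, t + r)))
            # around-the-loop coverage entering from the endpoints
            if da is not None:
                pieces.append((0.0, min(t, budget_m - da)))
            if db is not None:
                pieces.append((max(t, L - (budget_m - db)), L))
        else:
            if da is not None and budget_m > da:
                pieces.append((0.0, min(L, budget_m - da)))
            if db is not None and budget_m > db:
                pieces.append((max(0.0, L - (budget_m - db)), L))
        merged = _merge(pieces)
        if merged:
            intervals[eid] = merged
    return intervals, dist


def _union_intervals(parts: list[dict[int, Intervals]]) -> dict[int, Intervals]:
    out: dict[int, Intervals] = {}
    for part in parts:
        for eid, iv in part.items():
            out.setdefault(eid, []).extend(iv)
    return {eid: _merge(iv) for eid, iv in out.items()}


def _fractions(network: StreetNetwork, intervals: dict[int, Intervals]) -> dict[int, float]:
    return {eid: min(1.0, sum(e - s for s, e in iv) / network.edges[eid].length_m)
            for eid, iv in intervals.items()}


def polygonize_reach(reached_edges: dict[int, float | Intervals], network: StreetNetwork,
                     buffer_m: float = DEFAULT_BUFFER_M, quad_segs: int = 32):
    """Dilate the reached edge portions by ``buffer_m`` and union them.

    Values may be fractions in (0, 1] (clipped from the node_a end) or
    explicit along-edge ``(start_m, end_m)`` interval lists. Returns
    ``(polygon, area_km2)``. Dilation (not a convex hull) keeps unreached
    gaps out of the polygon, which is the point of edge-effect control.
    """
    if not reached_edges:
        raise ValueError("cannot polygonize an empty reach")
    if buffer_m <= 0:
        raise ValueError("buffer_m must be positive")
    pieces = []
    for eid, spec in reached_edges.items():
        line = network.edge_geometry(eid)
        if isinstance(spec, (int, float)):
            f = float(spec)
            if not 0 < f <= 1:
                raise ValueError(f"edge {eid}: reached fraction {f} outside (0, 1]")
            geom = line if f >= 1.0 else substring(line, 0.0, f * line.length)
            pieces.append(geom)
        else:
            for s, e in spec:
                pieces.append(substring(line, max(0.0, s), min(line.length, e)))
    poly = union_all([g.buffer(buffer_m, quad_segs=quad_segs) for g in pieces])
    return poly, poly.area / 1e6


def _build_area(outlet: FoodOutlet, mode: str, network: StreetNetwork,
                intervals: dict[int, Intervals], buffer_m: float) -> ServiceArea:
    if not intervals:
        raise ValueError(f"outlet {outlet.id}: empty {mode} reach")
    poly, area = polygonize_reach(intervals, network, buffer_m=buffer_m)
    sa = ServiceArea(outlet_id=outlet.id, mode=mode,
                     reached_edges=_fractions(network, intervals),
                     polygon=poly, area_km2=area)
    sa.reached_intervals = intervals  # along-edge placement, kept for clipping
    return sa


def walk_service_area(outlet: FoodOutlet, network: StreetNetwork,
                      max_dist_km: float = WALK_DIST_KM,
                      buffer_m: float = DEFAULT_BUFFER_M) -> ServiceArea:
    """0.40 km pedestrian-network reach around the outlet."""
    try:
        eid, off, _ = snap_to_network((outlet.x, outlet.y), network, pedestrian_only=True)
    except SnapError as exc:
        raise SnapError(f"outlet {outlet.id}: {exc}") from None
    intervals, _ = network_reach(network, eid, off, max_dist_km * 1000.0, pedestrian_only=True)
    return _build_area(outlet, "walk", network, intervals, buffer_m)


def bike_service_area(outlet: FoodOutlet, network: StreetNetwork,
                      max_dist_km: float = BIKE_DIST_KM,
                      buffer_m: float = DEFAULT_BUFFER_M) -> ServiceArea:
    """8.04 km full-network reach around the outlet."""
    try:
        eid, off, _ = snap_to_network((outlet.x, outlet.y), network, pedestrian_only=False)
    except SnapError as exc:
        raise SnapError(f"outlet {outlet.id}: {exc}") from None
    intervals, _ = network_reach(network, eid, off, max_dist_km * 1000.0, pedestrian_only=False)
    return _build_area(outlet, "bike", network, intervals, buffer_m)


def transit_service_area(outlet: FoodOutlet, network: StreetNetwork, transit: TransitSystem,
                         along_dist_km: float = TRANSIT_ALONG_KM,
                         stop_dist_km: float = TRANSIT_STOP_KM,
                         buffer_m: float = DEFAULT_BUFFER_M) -> ServiceArea:
    """Walk -> single-route ride -> walk composition (no transfers).

    If no stop lies within ``stop_dist_km`` walking of the outlet the area
    degenerates to the plain walking area.
    """
    try:
        eid, off, _ = snap_to_network((outlet.x, outlet.y), network, pedestrian_only=True)
    except SnapError as exc:
        raise SnapError(f"outlet {outlet.id}: {exc}") from None
    stop_m = stop_dist_km * 1000.0
    walk_iv, dist = network_reach(network, eid, off, stop_m, pedestrian_only=True)
    parts = [walk_iv]

    # boarding stops: walk distance from the outlet <= stop_dist
    boardable = {sid for sid, nid in transit.stops.items()
                 if dist.get(nid, math.inf) <= stop_m}
    reach_nodes: set[int] = set()
    for stop_ids, cds in zip(transit.routes, transit.cumdist_m):
        on_route = [(k, sid) for k, sid in enumerate(stop_ids) if sid in boardable]
        for k0, _sid in on_route:
            for k, sid in enumerate(stop_ids):
                if abs(cds[k] - cds[k0]) <= along_dist_km * 1000.0:
                    reach_nodes.add(transit.stops[sid])
    incident: dict[int, tuple[int, float]] = {}
    for seid, e in network.edges.items():
        if not e.pedestrian:
            continue
        incident.setdefault(e.node_a, (seid, 0.0))
        incident.setdefault(e.node_b, (seid, e.length_m))
    for nid in sorted(reach_nodes):
        if nid not in incident:  # isolated stop node: no walkable egress
            continue
        seid, soff = incident[nid]
        iv, _ = network_reach(network, seid, soff, stop_m, pedestrian_only=True)
        parts.append(iv)
    return _build_area(outlet, "transit", network, _union_intervals(parts), buffer_m)


def city_service_areas(city: CityBundle, mode: str,
                       buffer_m: float = DEFAULT_BUFFER_M) -> list[ServiceArea]:
    """Service areas of every outlet in the bundle for one mode."""
    if mode == "walk":
        return [walk_service_area(o, city.network, buffer_m=buffer_m) for o in city.outlets]
    if mode == "bike":
        return [bike_service_area(o, city.network, buffer_m=buffer_m) for o in city.outlets]
    if mode == "transit":
        return [transit_service_area(o, city.network, city.transit, buffer_m=buffer_m)
                for o in city.outlets]
    raise ValueError(f"unknown mode {mode!r}")
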