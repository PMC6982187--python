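"""Core domain types shared across the pipeline.

All coordinates are planar meters in an abstract projected frame; there is
no geographic CRS handling anywhere in the package. Distances between
outlets are network shortest paths (kilometers) except where a method
explicitly calls for Euclidean distance (the spatial-weights matrices used
by Moran's I and the spatial lag model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx
from shapely.geometry import LineString, Point, Polygon
from shapely.geometry.base import BaseGeometry

__all__ = [
    "StreetNetwork",
    "TransitSystem",
    "FoodOutlet",
    "CovariateZone",
    "CityBundle",
    "ServiceArea",
    "Edge",
]


@dataclass(frozen=True)
class Edge:
    """An undirected street segment between two network nodes."""

    node_a: int
    node_b: int
    length_m: float
    pedestrian: bool = True
    auto: bool = True

    def __post_init__(self) -> None:
        if self.length_m <= 0:
            raise ValueError(f"edge ({self.node_a},{self.node_b}) has non-positive length")


class StreetNetwork:
    """Planar street network: node coordinates plus undirected edges.

    Parameters
    ----------
    nodes : dict mapping node id -> (x, y) in meters.
    edges : dict mapping edge id -> :class:`Edge`.
    """

    def __init__(self, nodes: dict[int, tuple[float, float]], edges: dict[int, Edge]):
        self.nodes = dict(nodes)
        self.edges = dict(edges)
        for eid, e in self.edges.items():
            if e.node_a not in self.nodes or e.node_b not in self.nodes:
                raise ValueError(f"edge {eid} references unknown node")
        self._graph_cache: dict[bool, nx.Graph] = {}

    def to_networkx(self, pedestrian_only: bool = False) -> nx.Graph:
        """Return an undirected graph with ``length_m`` edge weights.

        The graph is cached; callers must not mutate it.
        """
        if pedestrian_only not in self._graph_cache:
            g = nx.Graph()
            g.add_nodes_from(self.nodes)
            for eid, e in self.edges.items():
                if pedestrian_only and not e.pedestrian:
                    continue
                g.add_edge(e.node_a, e.node_b, length_m=e.length_m, edge_id=eid)
            self._graph_cache[pedestrian_only] = g
        return self._graph_cache[pedestrian_only]

    def edge_geometry(self, edge_id: int) -> LineString:
        e = self.edges[edge_id]
        return LineString([self.nodes[e.node_a], self.nodes[e.node_b]])

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class TransitSystem:
    """Mass-transit routes over the street network.

    Each route is an ordered list of stop ids with a parallel list of
    strictly increasing cumulative along-route distances in meters. Every
    stop maps to an existing network node.
    """

    routes: list[list[int]]
    cumdist_m: list[list[float]]
    stops: dict[int, int]  # stop id -> network node id

    def validate(self, network: StreetNetwork) -> None:
        for r, (stop_ids, cds) in enumerate(zip(self.routes, self.cumdist_m)):
            if len(stop_ids) != len(cds):
                raise ValueError(f"route {r}: stop/distance length mismatch")
            for a, b in zip(cds, cds[1:]):
                if not b > a:
                    raise ValueError(f"route {r}: cumulative distances not strictly increasing")
        for sid, nid in self.stops.items():
            if nid not in network.nodes:
                raise ValueError(f"stop {sid} maps to unknown node {nid}")


@dataclass(frozen=True)
class FoodOutlet:
    """A food outlet: restaurant (efo_type=1) or grocer (efo_type=0).

    Revenue (USD/year) and floor area (sq ft) feed the revealed-accessibility
    weight w = revenue / floor_area, normalized across outlets.
    """

    id: int
    x: float
    y: float
    efo_type: int
    revenue_usd: float
    floor_area_sqft: float

    def __post_init__(self) -> None:
        if self.efo_type not in (0, 1):
            raise ValueError("efo_type must be 0 (grocer) or 1 (restaurant)")
        if self.revenue_usd <= 0:
            raise ValueError(f"outlet {self.id}: revenue must be positive")
        if self.floor_area_sqft <= 0:
            raise ValueError(f"outlet {self.id}: floor area must be positive")

    @property
    def point(self) -> Point:
        return Point(self.x, self.y)


@dataclass
class CovariateZone:
    """A covariate zone (census-block-group stand-in).

    ``kinds`` declares each attribute extensive (counts, split with area)
    or intensive (means/rates, area-weighted averaged).
    """

    id: int
    polygon: Polygon
    attributes: dict[str, float]
    kinds: dict[str, str]

    def __post_init__(self) -> None:
        if self.polygon.is_empty or not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError(f"zone {self.id}: degenerate polygon")
        missing = set(self.attributes) - set(self.kinds)
        if missing:
            raise ValueError(f"zone {self.id}: attributes without declared kind: {missing}")
        bad = {k: v for k, v in self.kinds.items() if v not in ("extensive", "intensive")}
        if bad:
            raise ValueError(f"zone {self.id}: invalid kinds {bad}")


@dataclass
class CityBundle:
    """Everything the pipeline consumes for one city."""

    network: StreetNetwork
    transit: TransitSystem
    outlets: list[FoodOutlet]
    zones: list[CovariateZone]
    extent: tuple[float, float]  # (width, height) in meters

    def __iter__(self) -> Iterator[FoodOutlet]:
        return iter(self.outlets)

    @property
    def covariate_names(self) -> list[str]:
        return sorted(self.zones[0].attributes) if self.zones else []


@dataclass
class ServiceArea:
    """A mode-specific network service area around one outlet.

    ``reached_edges`` maps edge id to the reached fraction of its length in
    (0, 1]; ``polygon`` is the buffered union of the reached edge portions.
    """

    outlet_id: int
    mode: str
    reached_edges: dict[int, float]
    polygon: BaseGeometry
    area_km2: float

    def __post_init__(self) -> None:
        if self.mode not in ("walk", "transit", "bike"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.area_km2 <= 0:
            raise ValueError("service area has non-positive area")
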