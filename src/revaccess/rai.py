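"""Revealed Accessibility Index (RAI).

For outlet j with competitors k in scope K (|K| = m - 1):

    RAI_j = (1 / (m - 1)) * sum_{k in K} w_k * c_jk^(-2)

where w_k is competitor k's revenue per square foot, normalized by the
city-wide maximum (so w in (0, 1]), and c_jk is the network shortest-path
distance in km, floored at ``min_distance_km`` so co-located outlets cannot
blow the inverse-square decay up to infinity. The default competitor scope
is the outlets whose location falls inside j's mode-specific service-area
polygon ("all other food outlets" within the active-travel neighborhood);
an all-city scope is available by configuration. An outlet with no
competitor in scope gets RAI = 0 by convention (no revealed interaction).

The regression outcome is sqrt(RAI).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from shapely.geometry import Point

from .config import RAIConfig
from .service_areas import snap_to_network
from .types import CityBundle, FoodOutlet, ServiceArea, StreetNetwork

__all__ = ["DistanceMatrix", "outlet_weight", "outlet_weights", "network_distance_matrix",
           "compute_rai", "sqrt_transform", "build_access_records", "AccessRecord"]


@dataclass
class DistanceMatrix:
    """All-pairs network shortest-path distances between outlets, km.

    Symmetric with a zero diagonal; disconnected pairs carry +inf and are
    excluded from RAI sums.
    """

    ids: list[int]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")

    def distance(self, i: int, j: int) -> float:
        return float(self.d[self.ids.index(i), self.ids.index(j)])


@dataclass
class AccessRecord:
    """One regression row: outlet x mode with RAI and per-km² covariates."""

    outlet_id: int
    mode: str
    rai: float
    rai_sqrt: float
    efo_type: int
    area_km2: float
    covariates: dict[str, float] = field(default_factory=dict)
    x: float = 0.0
    y: float = 0.0


def outlet_weights(outlets: list[FoodOutlet], normalization: str = "max") -> np.ndarray:
    """Usage weights w_k = (revenue_k / floor_area_k), max-normalized by default."""
    for o in outlets:
        if o.floor_area_sqft <= 0:
            raise ValueError(f"outlet {o.id}: floor area must be positive")
    raw = np.array([o.revenue_usd / o.floor_area_sqft for o in outlets])
    if normalization == "max":
        return raw / raw.max()
    if normalization == "none":
        return raw
    raise ValueError(f"unknown normalization {normalization!r}")


def outlet_weight(outlet: FoodOutlet, all_outlets: list[FoodOutlet],
                  normalization: str = "max") -> float:
    """Weight of one outlet relative to the full outlet set."""
    w = outlet_weights(all_outlets, normalization)
    return float(w[[o.id for o in all_outlets].index(outlet.id)])


def network_distance_matrix(outlets: list[FoodOutlet], network: StreetNetwork) -> DistanceMatrix:
    """Repeated single-source Dijkstra between outlet snap nodes, in km.

    Outlets snap to their nearest network node (generated cities place them
    on nodes, so this is exact there). Pairs in different components get
    +inf with a warning.
    """
    xy = np.array([[x, y] for x, y in (network.nodes[n] for n in sorted(network.nodes))])
    node_ids = sorted(network.nodes)
    snap_nodes = []
    for o in outlets:
        # nearest node; validate against the 100 m edge-snap tolerance
        snap_to_network((o.x, o.y), network)
        d2 = ((xy - [o.x, o.y]) ** 2).sum(axis=1)
        snap_nodes.append(node_ids[int(np.argmin(d2))])
    g = network.to_networkx()
    n = len(outlets)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    cache: dict[int, dict[int, float]] = {}
    for i, src in enumerate(snap_nodes):
        if src not in cache:
            cache[src] = nx.single_source_dijkstra_path_length(g, src, weight="length_m")
        lengths = cache[src]
        for j, dst in enumerate(snap_nodes):
            if dst in lengths:
                d[i, j] = lengths[dst] / 1000.0
    d = 0.5 * (d + d.T)  # symmetrize float round-off
    np.fill_diagonal(d, 0.0)
    if np.isinf(d).any():
        warnings.warn("disconnected outlet pairs: distances set to +inf and "
                      "excluded from RAI sums", stacklevel=2)
    return DistanceMatrix(ids=[o.id for o in outlets], d=d)


def compute_rai(j: int, outlets: list[FoodOutlet], dmatrix: DistanceMatrix,
                service_area: ServiceArea | None, config: RAIConfig | None = None) -> float:
    """RAI of outlet j. ``service_area`` must be j's own area when the scope
    is ``same_service_area``; it may be None for ``all_city`` scope."""
    config = config or RAIConfig()
    pos = {oid: idx for idx, oid in enumerate(dmatrix.ids)}
    ji = pos[j]
    if config.competitor_scope == "same_service_area":
        if service_area is None:
            raise ValueError("same_service_area scope requires j's service area")
        if service_area.outlet_id != j:
            raise ValueError(f"service area belongs to outlet {service_area.outlet_id}, not {j}")
        in_scope = [pos[o.id] for o in outlets
                    if o.id != j and service_area.polygon.covers(Point(o.x, o.y))]
    else:
        in_scope = [pos[o.id] for o in outlets if o.id != j]
    if not in_scope:
        return 0.0
    w_all = outlet_weights(outlets, config.weight_normalization)
    w = {pos[o.id]: w_all[idx] for idx, o in enumerate(outlets)}
    total = 0.0
    n_used = 0
    for k in in_scope:
        c = dmatrix.d[ji, k]
        if math.isinf(c):
            continue
        c = max(c, config.min_distance_km)
        total += w[k] * c ** config.decay_exponent
        n_used += 1
    if n_used == 0:
        warnings.warn(f"outlet {j}: all in-scope competitors disconnected; RAI over "
                      "finite distances only (none)", stacklevel=2)
        return 0.0
    return total / len(in_scope)


def sqrt_transform(rai: float) -> float:
    """Square-root transform of the index (the regression outcome)."""
    if rai < 0:
        raise ValueError("RAI must be nonnegative")
    return math.sqrt(rai)


def build_access_records(city: CityBundle, areas: list[ServiceArea],
                         covariate_rows: list[dict[str, float]],
                         dmatrix: DistanceMatrix | None = None,
                         config: RAIConfig | None = None) -> list[AccessRecord]:
    """Assemble one AccessRecord per (outlet, mode) from precomputed pieces."""
    config = config or RAIConfig()
    if dmatrix is None:
        dmatrix = network_distance_matrix(city.outlets, city.network)
    by_id = {o.id: o for o in city.outlets}
    records = []
    for area, cov in zip(areas, covariate_rows):
        o = by_id[area.outlet_id]
        r = compute_rai(o.id, city.outlets, dmatrix, area, config)
        records.append(AccessRecord(
            outlet_id=o.id, mode=area.mode, rai=r, rai_sqrt=sqrt_transform(r),
            efo_type=o.efo_type, area_km2=area.area_km2,
            covariates=dict(cov), x=o.x, y=o.y))
    return records
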