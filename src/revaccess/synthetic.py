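"""Seedable synthetic-city generator.

Generates a perturbed-grid street network, a small mass-transit system,
food outlets (restaurants and grocers) with lognormal revenue and floor
area, and covariate zones tiling the extent, with attributes drawn from
spatially correlated Gaussian fields. Every component draws from its own
random stream derived from the master seed, so e.g. adding outlets never
changes the network.

A spatially autocorrelated outcome can be planted on any point set with
:func:`plant_sar_outcome` (the simulation inverse of the spatial lag
model), which estimator-recovery experiments use as ground truth.
"""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import Polygon

from .config import SyntheticCityConfig, CovariateSpec
from .spatial import inverse_distance_weights
from .types import CityBundle, CovariateZone, Edge, FoodOutlet, StreetNetwork, TransitSystem

__all__ = [
    "generate_city",
    "generate_street_network",
    "generate_transit",
    "generate_outlets",
    "generate_covariate_zones",
    "plant_sar_outcome",
    "clustered_coords",
]

# Spawn keys of the per-component random streams.
_STREAMS = {"network": 0, "transit": 1, "outlets": 2, "zones": 3, "outcome": 4}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[component],)))


def generate_street_network(cfg: SyntheticCityConfig) -> StreetNetwork:
    """Perturbed grid graph: nodes at grid points jittered by
    ``edge_jitter * grid_spacing``, 4-neighbor edges with Euclidean lengths.

    Jitter < 0.5 spacing keeps the planar embedding crossing-free and every
    edge length within 1.5x the node spacing, and the grid is connected by
    construction.
    """
    rng = _rng(cfg.seed, "network")
    w, h = cfg.extent
    s = cfg.grid_spacing
    nx_, ny_ = int(round(w / s)) + 1, int(round(h / s)) + 1
    nodes: dict[int, tuple[float, float]] = {}
    for i in range(nx_):
        for j in range(ny_):
            nid = i * ny_ + j
            jx, jy = rng.uniform(-cfg.edge_jitter * s, cfg.edge_jitter * s, size=2)
            x = min(max(i * s + jx, 0.0), w)
            y = min(max(j * s + jy, 0.0), h)
            nodes[nid] = (x, y)
    edges: dict[int, Edge] = {}
    eid = 0
    for i in range(nx_):
        for j in range(ny_):
            a = i * ny_ + j
            for di, dj in ((1, 0), (0, 1)):
                if i + di < nx_ and j + dj < ny_:
                    b = (i + di) * ny_ + (j + dj)
                    length = math.dist(nodes[a], nodes[b])
                    edges[eid] = Edge(a, b, length)
                    eid += 1
    return StreetNetwork(nodes, edges)


def generate_transit(cfg: SyntheticCityConfig, network: StreetNetwork) -> TransitSystem:
    """Straight bus lines along alternating grid rows/columns.

    Stops are placed on route nodes every ~``stop_spacing`` meters;
    cumulative distances accumulate the along-route edge lengths, so they
    are consistent with the street network the route runs on.
    """
    rng = _rng(cfg.seed, "transit")
    w, h = cfg.extent
    s = cfg.grid_spacing
    nx_, ny_ = int(round(w / s)) + 1, int(round(h / s)) + 1
    step = max(1, int(round(cfg.stop_spacing / s)))

    routes: list[list[int]] = []
    cumdists: list[list[float]] = []
    stops: dict[int, int] = {}
    stop_id = 0
    for r in range(cfg.n_transit_routes):
        if r % 2 == 0:  # horizontal route along a random grid row
            j = int(rng.integers(1, max(2, ny_ - 1)))
            path = [i * ny_ + j for i in range(nx_)]
        else:  # vertical route along a random grid column
            i = int(rng.integers(1, max(2, nx_ - 1)))
            path = [i * ny_ + j for j in range(ny_)]
        cum = [0.0]
        for a, b in zip(path, path[1:]):
            cum.append(cum[-1] + math.dist(network.nodes[a], network.nodes[b]))
        stop_idx = list(range(0, len(path), step))
        if stop_idx[-1] != len(path) - 1:
            stop_idx.append(len(path) - 1)
        route_stops = []
        route_cd = []
        for k in stop_idx:
            stops[stop_id] = path[k]
            route_stops.append(stop_id)
            route_cd.append(cum[k])
            stop_id += 1
        routes.append(route_stops)
        cumdists.append(route_cd)
    ts = TransitSystem(routes, cumdists, stops)
    ts.validate(network)
    return ts


def generate_outlets(cfg: SyntheticCityConfig, network: StreetNetwork) -> list[FoodOutlet]:
    """Outlets snapped to distinct network nodes (restaurants first),
    with lognormal annual revenue and floor area."""
    n_total = cfg.n_restaurants + cfg.n_grocers
    if n_total < 1:
        raise ValueError("at least one outlet required (n_restaurants + n_grocers >= 1)")
    rng = _rng(cfg.seed, "outlets")
    node_ids = np.array(sorted(network.nodes))
    replace = n_total > len(node_ids)
    chosen = rng.choice(node_ids, size=n_total, replace=replace)
    mu_r, sd_r = cfg.revenue_lognormal
    mu_s, sd_s = cfg.sqft_lognormal
    revenue = rng.lognormal(mu_r, sd_r, size=n_total)
    sqft = rng.lognormal(mu_s, sd_s, size=n_total)
    outlets = []
    for k in range(n_total):
        x, y = network.nodes[int(chosen[k])]
        outlets.append(FoodOutlet(
            id=k, x=x, y=y,
            efo_type=1 if k < cfg.n_restaurants else 0,
            revenue_usd=float(revenue[k]),
            floor_area_sqft=float(sqft[k]),
        ))
    return outlets


def _zone_grid(n_zones: int, extent: tuple[float, float]) -> list[Polygon]:
    """Tile the extent with exactly ``n_zones`` rectangles.

    Rows of equal height; row i carries ``base`` or ``base+1`` columns so the
    counts sum exactly to n_zones, and each row's columns share its width
    evenly — the union is the extent exactly (up to float rounding).
    """
    w, h = extent
    ny = max(1, int(math.floor(math.sqrt(n_zones))))
    base, extra = divmod(n_zones, ny)
    polys = []
    row_h = h / ny
    for r in range(ny):
        ncols = base + (1 if r < extra else 0)
        col_w = w / ncols
        y0, y1 = r * row_h, (r + 1) * row_h
        for c in range(ncols):
            x0, x1 = c * col_w, (c + 1) * col_w
            polys.append(Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)]))
    return polys


def _correlated_fields(specs: list[CovariateSpec], centroids: np.ndarray,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Latent standard-normal fields per covariate, with optional pairwise
    correlation injected at the white-noise stage and spatial structure by
    Gaussian-kernel smoothing (a cheap Gaussian-random-field stand-in).

    Smoothing weights are normalized by sqrt(sum k^2) so the smoothed field
    keeps unit marginal variance, and the same kernel is linear in the
    noise, so injected cross-correlations survive smoothing when ranges
    match.
    """
    n = len(centroids)
    d2 = ((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    raw: dict[str, np.ndarray] = {}
    fields: dict[str, np.ndarray] = {}
    for spec in specs:
        z = rng.standard_normal(n)
        if spec.correlate_with is not None:
            if spec.correlate_with not in raw:
                raise ValueError(
                    f"covariate {spec.name}: correlate_with {spec.correlate_with!r} "
                    "must be defined earlier in the list")
            r = spec.correlation
            z = r * raw[spec.correlate_with] + math.sqrt(1 - r * r) * z
        raw[spec.name] = z
        if spec.spatial_range > 0:
            k = np.exp(-d2 / (2.0 * spec.spatial_range ** 2))
            smooth = k @ z / np.sqrt((k ** 2).sum(axis=1))
        else:
            smooth = z
        fields[spec.name] = smooth
    return fields


def generate_covariate_zones(cfg: SyntheticCityConfig,
                             extent: tuple[float, float] | None = None) -> list[CovariateZone]:
    """Zones tiling the extent with spatially correlated attributes.

    Each attribute is ``mean + sd * field`` where ``field`` is a unit-variance
    spatially smoothed Gaussian field at the zone centroids; values are
    clipped at zero when the spec asks for it.
    """
    if cfg.n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    extent = extent or cfg.extent
    rng = _rng(cfg.seed, "zones")
    polys = _zone_grid(cfg.n_zones, extent)
    centroids = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    fields = _correlated_fields(cfg.covariates, centroids, rng)
    kinds = {s.name: s.kind for s in cfg.covariates}
    zones = []
    for i, poly in enumerate(polys):
        attrs = {}
        for spec in cfg.covariates:
            v = spec.mean + spec.sd * fields[spec.name][i]
            if spec.clip_nonneg:
                v = max(v, 0.0)
            attrs[spec.name] = float(v)
        zones.append(CovariateZone(id=i, polygon=poly, attributes=attrs, kinds=dict(kinds)))
    return zones


def generate_city(cfg: SyntheticCityConfig) -> CityBundle:
    """Generate a full city bundle; deterministic under ``cfg.seed``."""
    if cfg.n_restaurants + cfg.n_grocers < 1:
        raise ValueError("at least one outlet required")
    network = generate_street_network(cfg)
    transit = generate_transit(cfg, network)
    outlets = generate_outlets(cfg, network)
    zones = generate_covariate_zones(cfg)
    return CityBundle(network=network, transit=transit, outlets=outlets,
                      zones=zones, extent=cfg.extent)


def clustered_coords(seed: int | np.random.Generator, n: int = 200,
                     n_clusters: int = 40, extent: float = 10_000.0,
                     spread: float = 30.0) -> np.ndarray:
    """Clustered point locations emulating commercial-corridor clustering.

    Food outlets concentrate in corridors and centers rather than spreading
    uniformly; cluster structure also keeps inverse-distance spatial
    weights close to block-local, which is what identifies the spatial lag
    parameter in recovery experiments (uniformly scattered points make the
    row-standardized inverse-distance matrix nearly rank-one and rho
    weakly identified).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = rng.uniform(0, extent, size=(n_clusters, 2))
    idx = rng.integers(0, n_clusters, size=n)
    return centers[idx] + rng.normal(0, spread, size=(n, 2))


def plant_sar_outcome(coords: np.ndarray, X: np.ndarray, rho: float, beta: np.ndarray,
                      sigma: float, seed: int | np.random.Generator) -> np.ndarray:
    """Simulate y = (I - rho W)^-1 (X beta + eps), eps ~ N(0, sigma^2).

    W is the row-standardized inverse-Euclidean-distance matrix of
    ``coords`` — the exact inverse of the spatial lag model, so maximum
    likelihood on (y, X, W) should recover (rho, beta).

    ``rho`` must lie strictly inside the stability interval
    (1/lambda_min, 1/lambda_max) given by W's extreme eigenvalues.
    """
    coords = np.asarray(coords, dtype=float)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n = len(coords)
    if X.shape != (n, len(beta)):
        raise ValueError(f"X shape {X.shape} incompatible with coords ({n}) and beta ({len(beta)})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rho == 0.0:  # identity case: no weights needed
        return X @ beta + rng.standard_normal(n) * sigma
    W = inverse_distance_weights(coords).row_standardized().W
    lam = np.linalg.eigvals(W)
    lam = lam.real[np.abs(lam.imag) < 1e-8] if np.iscomplexobj(lam) else lam
    lo = 1.0 / lam.min() if lam.min() < 0 else -np.inf
    hi = 1.0 / lam.max() if lam.max() > 0 else np.inf
    if not lo < rho < hi:
        raise ValueError(f"rho={rho} outside the stable interval ({lo:.4f}, {hi:.4f})")
    signal = X @ beta + rng.standard_normal(n) * sigma
    return np.linalg.solve(np.eye(n) - rho * W, signal)
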