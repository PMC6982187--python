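"""Areal interpolation of zonal covariates onto service areas, per-km²
normalization, and kernel density surfaces.

Extensive attributes (counts) transfer in proportion to the area of
overlap and are then divided by the service-area size; intensive
attributes (means, rates) are area-weighted averages and are never
densified — dividing a mean by an area would be dimensionally wrong.
Intersections are exact polygon intersections, so extensive totals are
conserved over any partition of the extent (the pycnophylactic property).
"""

from __future__ import annotations

import numpy as np
from shapely import STRtree
from shapely.geometry.base import BaseGeometry

from .types import CovariateZone, ServiceArea

__all__ = ["areal_interpolate", "per_km_density", "kde", "interpolate_all",
           "service_area_covariates"]


def areal_interpolate(zones: list[CovariateZone], target: BaseGeometry,
                      attribute: str, kind: str | None = None) -> float:
    """Transfer one zonal attribute onto ``target`` by area weighting.

    extensive: sum of value_z * area(z ∩ target) / area(z);
    intensive: area-of-overlap weighted mean over intersecting zones.

    Raises if the target intersects no zone — silently returning 0 would
    hide misaligned geometry.
    """
    if target.is_empty or not target.is_valid:
        raise ValueError("target polygon is empty or invalid")
    if not zones:
        raise ValueError("no zones supplied")
    k = kind or zones[0].kinds.get(attribute)
    if k not in ("extensive", "intensive"):
        raise ValueError(f"unknown attribute kind {k!r}")
    num = 0.0
    wsum = 0.0
    hit = False
    for z in zones:
        if attribute not in z.attributes:
            raise KeyError(f"zone {z.id} lacks attribute {attribute!r}")
        a = z.polygon.intersection(target).area
        if a <= 0:
            continue
        hit = True
        if k == "extensive":
            num += z.attributes[attribute] * a / z.polygon.area
        else:
            num += z.attributes[attribute] * a
            wsum += a
    if not hit:
        raise ValueError("target polygon is disjoint from every zone")
    return num / wsum if k == "intensive" else num


def per_km_density(value: float, area_km2: float) -> float:
    """Normalize an interpolated total by the service-area size (km²).

    Per-unit-area normalization is the MAUP control: totals from
    differently sized service areas become comparable densities.
    """
    if area_km2 <= 0:
        raise ValueError("area_km2 must be positive")
    return value / area_km2


def service_area_covariates(zones: list[CovariateZone], area: ServiceArea,
                            tree: STRtree | None = None,
                            zone_geoms: list | None = None) -> dict[str, float]:
    """All covariates of one service area: extensive attributes interpolated
    then densified per km²; intensive attributes area-weighted averaged."""
    if tree is not None and zone_geoms is not None:
        idx = tree.query(area.polygon)
        cand = [zones[i] for i in sorted(idx)]
    else:
        cand = zones
    names = zones[0].attributes.keys()
    kinds = zones[0].kinds
    out: dict[str, float] = {}
    for name in names:
        v = areal_interpolate(cand, area.polygon, name)
        out[name] = per_km_density(v, area.area_km2) if kinds[name] == "extensive" else v
    return out


def interpolate_all(zones: list[CovariateZone], areas: list[ServiceArea]) -> list[dict[str, float]]:
    """Covariate rows for a list of service areas (one dict per area)."""
    geoms = [z.polygon for z in zones]
    tree = STRtree(geoms)
    return [service_area_covariates(zones, a, tree=tree, zone_geoms=geoms) for a in areas]


def kde(points: np.ndarray, weights: np.ndarray | None = None,
        bandwidth_m: float = 500.0, cell_m: float = 50.0,
        bounds: tuple[float, float, float, float] | None = None,
        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted Gaussian kernel density surface on a regular grid.

    Returns ``(grid, xs, ys)`` where ``grid[i, j]`` is the density
    (weight per m²) at cell center ``(xs[j], ys[i])``. The surface
    integrates to the total weight when the grid pad (4 bandwidths) holds
    essentially all kernel mass and bandwidth >> cell size.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("kde requires at least one point")
    if bandwidth_m <= 0 or cell_m <= 0:
        raise ValueError("bandwidth_m and cell_m must be positive")
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != len(pts):
        raise ValueError("weights length must match points")
    if bounds is None:
        pad = 4.0 * bandwidth_m
        bounds = (pts[:, 0].min() - pad, pts[:, 1].min() - pad,
                  pts[:, 0].max() + pad, pts[:, 1].max() + pad)
    x0, y0, x1, y1 = bounds
    xs = np.arange(x0 + cell_m / 2, x1, cell_m)
    ys = np.arange(y0 + cell_m / 2, y1, cell_m)
    # separable Gaussian: outer product of per-axis kernel matrices
    kx = np.exp(-0.5 * ((xs[None, :] - pts[:, 0][:, None]) / bandwidth_m) ** 2)
    ky = np.exp(-0.5 * ((ys[None, :] - pts[:, 1][:, None]) / bandwidth_m) ** 2)
    norm = 1.0 / (2.0 * np.pi * bandwidth_m ** 2)
    grid = norm * np.einsum("p,pi,pj->ij", w, ky, kx)
    return grid, xs, ys
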