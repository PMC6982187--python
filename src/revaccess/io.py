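"""GeoJSON / CSV serialization of city bundles, service areas and access
records.

GeoJSON is plain JSON with geometries handled by shapely's
``mapping``/``shape``; coordinates are planar meters (no CRS member is
written). Serialization is deterministic: keys are sorted and floats use
Python's shortest-repr formatting, so identical bundles produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .rai import AccessRecord
from .types import (CityBundle, CovariateZone, Edge, FoodOutlet, ServiceArea,
                    StreetNetwork, TransitSystem)

__all__ = ["write_city", "read_city", "write_service_areas", "read_service_areas",
           "records_to_dataframe", "write_access_records", "read_access_records",
           "dump_geojson"]


def dump_geojson(features: list[dict], path: str | Path) -> None:
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n")


def _feature(geom, props: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": props}


def write_city(city: CityBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a bundle as four GeoJSON files plus a zone-attribute CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    feats = []
    for eid in sorted(city.network.edges):
        e = city.network.edges[eid]
        feats.append(_feature(city.network.edge_geometry(eid), {
            "edge_id": eid, "node_a": e.node_a, "node_b": e.node_b,
            "length_m": e.length_m,
            "modes": ([*(["pedestrian"] if e.pedestrian else []),
                       *(["auto"] if e.auto else [])]),
        }))
    paths["network"] = outdir / "network.geojson"
    dump_geojson(feats, paths["network"])

    feats = []
    from shapely.geometry import LineString, Point
    for r, (stop_ids, cds) in enumerate(zip(city.transit.routes, city.transit.cumdist_m)):
        pts = [city.network.nodes[city.transit.stops[s]] for s in stop_ids]
        feats.append(_feature(LineString(pts), {"route": r, "kind": "route"}))
        for s, cd in zip(stop_ids, cds):
            feats.append(_feature(Point(city.network.nodes[city.transit.stops[s]]), {
                "route": r, "kind": "stop", "stop_id": s,
                "node_id": city.transit.stops[s], "cumdist_m": cd}))
    paths["transit"] = outdir / "transit.geojson"
    dump_geojson(feats, paths["transit"])

    feats = [_feature(o.point, {"outlet_id": o.id, "efo_type": o.efo_type,
                                "revenue_usd": o.revenue_usd,
                                "floor_area_sqft": o.floor_area_sqft})
             for o in city.outlets]
    paths["outlets"] = outdir / "outlets.geojson"
    dump_geojson(feats, paths["outlets"])

    feats = [_feature(z.polygon, {"zone_id": z.id, "attributes": z.attributes,
                                  "kinds": z.kinds})
             for z in city.zones]
    paths["zones"] = outdir / "zones.geojson"
    dump_geojson(feats, paths["zones"])

    rows = [{"zone_id": z.id, **{k: z.attributes[k] for k in sorted(z.attributes)}}
            for z in city.zones]
    paths["zone_table"] = outdir / "zones.csv"
    pd.DataFrame(rows).to_csv(paths["zone_table"], index=False)

    meta = {"extent": list(city.extent), "schema": 1}
    paths["meta"] = outdir / "city.json"
    paths["meta"].write_text(json.dumps(meta, sort_keys=True) + "\n")
    return paths


def read_city(indir: str | Path) -> CityBundle:
    indir = Path(indir)

    def load(name):
        return json.loads((indir / name).read_text())["features"]

    nodes: dict[int, tuple[float, float]] = {}
    edges: dict[int, Edge] = {}
    for f in load("network.geojson"):
        p = f["properties"]
        (xa, ya), (xb, yb) = f["geometry"]["coordinates"][0], f["geometry"]["coordinates"][-1]
        nodes.setdefault(p["node_a"], (xa, ya))
        nodes.setdefault(p["node_b"], (xb, yb))
        edges[p["edge_id"]] = Edge(p["node_a"], p["node_b"], p["length_m"],
                                   pedestrian="pedestrian" in p["modes"],
                                   auto="auto" in p["modes"])
    network = StreetNetwork(nodes, edges)

    routes: dict[int, list[tuple[float, int]]] = {}
    stops: dict[int, int] = {}
    for f in load("transit.geojson"):
        p = f["properties"]
        if p["kind"] == "stop":
            stops[p["stop_id"]] = p["node_id"]
            routes.setdefault(p["route"], []).append((p["cumdist_m"], p["stop_id"]))
    route_list, cd_list = [], []
    for r in sorted(routes):
        entries = sorted(routes[r])
        route_list.append([s for _, s in entries])
        cd_list.append([cd for cd, _ in entries])
    transit = TransitSystem(route_list, cd_list, stops)
    transit.validate(network)

    outlets = []
    for f in load("outlets.geojson"):
        p = f["properties"]
        x, y = f["geometry"]["coordinates"]
        outlets.append(FoodOutlet(id=p["outlet_id"], x=x, y=y, efo_type=p["efo_type"],
                                  revenue_usd=p["revenue_usd"],
                                  floor_area_sqft=p["floor_area_sqft"]))
    outlets.sort(key=lambda o: o.id)

    zones = []
    for f in load("zones.geojson"):
        p = f["properties"]
        zones.append(CovariateZone(id=p["zone_id"], polygon=shape(f["geometry"]),
                                   attributes=p["attributes"], kinds=p["kinds"]))
    zones.sort(key=lambda z: z.id)

    meta = json.loads((indir / "city.json").read_text())
    return CityBundle(network=network, transit=transit, outlets=outlets, zones=zones,
                      extent=tuple(meta["extent"]))


def write_service_areas(areas: list[ServiceArea], path: str | Path) -> None:
    feats = [_feature(a.polygon, {"outlet_id": a.outlet_id, "mode": a.mode,
                                  "area_km2": a.area_km2,
                                  "reached_edges": {str(k): v for k, v
                                                    in sorted(a.reached_edges.items())}})
             for a in areas]
    dump_geojson(feats, path)


def read_service_areas(path: str | Path) -> list[ServiceArea]:
    feats = json.loads(Path(path).read_text())["features"]
    out = []
    for f in feats:
        p = f["properties"]
        poly = shape(f["geometry"])
        out.append(ServiceArea(outlet_id=p["outlet_id"], mode=p["mode"],
                               reached_edges={int(k): v for k, v in p["reached_edges"].items()},
                               polygon=poly, area_km2=p["area_km2"]))
    return out


def records_to_dataframe(records: list[AccessRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"outlet_id": r.outlet_id, "mode": r.mode, "rai": r.rai,
               "rai_sqrt": r.rai_sqrt, "efo_type": r.efo_type,
               "area_km2": r.area_km2, "x": r.x, "y": r.y}
        row.update({k: r.covariates[k] for k in sorted(r.covariates)})
        rows.append(row)
    return pd.DataFrame(rows)


def write_access_records(records: list[AccessRecord], path: str | Path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def read_access_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
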