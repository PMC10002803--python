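"""Plain-text readers and writers for scenario artifacts.

All tables are CSV with fixed headers; the road network is a node
table (node_id,x,y) plus an edge list (node_a,node_b,length_km,
speed_kmh).  An optional GeoJSON writer emits Point features for
facilities and tract centroids and LineString features for edges.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .synthetic import Facility, PopulationBlock, RoadNetwork, Tract

TRACT_COLUMNS = ["tract_id", "county", "population", "women_40_49",
                 "women_50_74", "women_over_74", "pct_black_women",
                 "deprivation", "pct_vehicle", "bus_stops",
                 "centroid_x", "centroid_y", "node_id"]
BLOCK_COLUMNS = ["block_id", "tract_id", "x", "y", "population"]
FACILITY_COLUMNS = ["facility_id", "county", "tract_id", "x", "y",
                    "units", "bicoe", "capacity", "node_id"]


def tracts_to_frame(tracts: Iterable[Tract]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(t, c) for c in TRACT_COLUMNS}
                         for t in tracts], columns=TRACT_COLUMNS)


def write_tracts(tracts: Iterable[Tract], path) -> None:
    tracts_to_frame(tracts).to_csv(path, index=False)


def read_tracts(path) -> list[Tract]:
    df = pd.read_csv(path)
    out = []
    for rec in df.to_dict("records"):
        nid = rec.get("node_id")
        out.append(Tract(
            tract_id=str(rec["tract_id"]), county=str(rec["county"]),
            population=int(rec["population"]),
            women_40_49=int(rec["women_40_49"]),
            women_50_74=int(rec["women_50_74"]),
            women_over_74=int(rec["women_over_74"]),
            pct_black_women=float(rec["pct_black_women"]),
            deprivation=float(rec["deprivation"]),
            pct_vehicle=float(rec["pct_vehicle"]),
            bus_stops=int(rec["bus_stops"]),
            centroid_x=float(rec["centroid_x"]),
            centroid_y=float(rec["centroid_y"]),
            node_id=None if pd.isna(nid) else int(nid)))
    return out


def write_blocks(blocks: Iterable[PopulationBlock], path) -> None:
    pd.DataFrame([{c: getattr(b, c) for c in BLOCK_COLUMNS} for b in blocks],
                 columns=BLOCK_COLUMNS).to_csv(path, index=False)


def read_blocks(path) -> list[PopulationBlock]:
    df = pd.read_csv(path)
    return [PopulationBlock(block_id=str(r["block_id"]),
                            tract_id=str(r["tract_id"]), x=float(r["x"]),
                            y=float(r["y"]), population=int(r["population"]))
            for r in df.to_dict("records")]


def write_facilities(facilities: Iterable[Facility], path) -> None:
    pd.DataFrame([{c: getattr(f, c) for c in FACILITY_COLUMNS}
                  for f in facilities],
                 columns=FACILITY_COLUMNS).to_csv(path, index=False)


def read_facilities(path) -> list[Facility]:
    df = pd.read_csv(path)
    out = []
    for rec in df.to_dict("records"):
        nid, tid, county = rec.get("node_id"), rec.get("tract_id"), rec.get("county")
        out.append(Facility(
            facility_id=str(rec["facility_id"]),
            x=float(rec["x"]), y=float(rec["y"]), units=int(rec["units"]),
            bicoe=bool(rec["bicoe"]), capacity=float(rec["capacity"]),
            county=None if pd.isna(county) else str(county),
            tract_id=None if pd.isna(tid) else str(tid),
            node_id=None if pd.isna(nid) else int(nid)))
    return out


def write_network(network: RoadNetwork, nodes_path, edges_path) -> None:
    pd.DataFrame(network.nodes, columns=["node_id", "x", "y"]
                 ).to_csv(nodes_path, index=False)
    pd.DataFrame(network.edges,
                 columns=["node_a", "node_b", "length_km", "speed_kmh"]
                 ).to_csv(edges_path, index=False)


def read_network(nodes_path, edges_path) -> RoadNetwork:
    nodes = [(int(r["node_id"]), float(r["x"]), float(r["y"]))
             for r in pd.read_csv(nodes_path).to_dict("records")]
    edges = [(int(r["node_a"]), int(r["node_b"]),
              float(r["length_km"]), float(r["speed_kmh"]))
             for r in pd.read_csv(edges_path).to_dict("records")]
    return RoadNetwork(nodes=nodes, edges=edges)


def scenario_geojson(tracts: Sequence[Tract], facilities: Sequence[Facility],
                     network: RoadNetwork) -> dict:
    """FeatureCollection of centroids, facilities and road edges."""
    xy = {n[0]: (n[1], n[2]) for n in network.nodes}
    features = []
    for t in tracts:
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [t.centroid_x, t.centroid_y]},
            "properties": {"kind": "tract_centroid", "tract_id": t.tract_id,
                           "county": t.county, "population": t.population},
        })
    for f in facilities:
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [f.x, f.y]},
            "properties": {"kind": "facility", "facility_id": f.facility_id,
                           "units": f.units, "bicoe": f.bicoe},
        })
    for a, b, length, speed in network.edges:
        features.append({
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [list(xy[a]), list(xy[b])]},
            "properties": {"kind": "road", "length_km": length,
                           "speed_kmh": speed},
        })
    return {"type": "FeatureCollection", "features": features}


def write_geojson(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True))
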