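"""Network drive times and drive-time catchment bands.

Travel times are exact shortest-path minutes over an undirected road
network whose edges are weighted by ``60 * length_km / speed_kmh``.
Tracts are classified into bands by their minimum drive time to any
site: bands are half-open on the left and closed on the right, so a
tract at exactly 15 minutes counts as ``within_15``.  Pairs with no
connecting path carry an infinite sentinel and land in the outermost
band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

UNREACHABLE = math.inf

__all__ = [
    "UNREACHABLE",
    "TravelMatrix",
    "CatchmentClassification",
    "edge_minutes",
    "travel_matrix",
    "classify_catchment",
    "catchment_summary",
]


def edge_minutes(length_km: float, speed_kmh: float) -> float:
    """Traversal time of one edge, in minutes."""
    if length_km <= 0:
        raise ValueError(f"length_km must be positive, got {length_km}")
    if speed_kmh <= 0:
        raise ValueError(f"speed_kmh must be positive, got {speed_kmh}")
    return 60.0 * length_km / speed_kmh


@dataclass
class TravelMatrix:
    """Origin-by-destination shortest-path times in minutes.

    ``minutes[i, j]`` is the drive time from ``origin_ids[i]`` to
    ``destination_ids[j]``; unreachable pairs hold ``inf``.
    """

    origin_ids: list
    destination_ids: list
    minutes: np.ndarray
    _orow: dict = field(default_factory=dict, repr=False)
    _dcol: dict = field(default_factory=dict, repr=False)
    _dest_order: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.origin_ids = list(self.origin_ids)
        self.destination_ids = list(self.destination_ids)
        self.minutes = np.asarray(self.minutes, dtype=float)
        if self.minutes.shape != (len(self.origin_ids), len(self.destination_ids)):
            raise ValueError("minutes shape does not match id lists")
        if np.any(self.minutes < 0):
            raise ValueError("travel times must be non-negative")
        self._orow = {o: i for i, o in enumerate(self.origin_ids)}
        self._dcol = {d: j for j, d in enumerate(self.destination_ids)}

    def time(self, origin, destination) -> float:
        return float(self.minutes[self._orow[origin], self._dcol[destination]])

    def row(self, origin) -> np.ndarray:
        return self.minutes[self._orow[origin]]

    def columns(self, destinations: Sequence) -> np.ndarray:
        idx = [self._dcol[d] for d in destinations]
        return self.minutes[:, idx]

    def sorted_destinations(self) -> np.ndarray:
        """Per-origin destination column indices in ascending (time, id) order.

        Cached; used by the allocator to scan sites nearest-first with a
        deterministic tie-break on destination id.
        """
        if self._dest_order is None:
            keys = np.array([str(d) for d in self.destination_ids])
            order = np.empty_like(self.minutes, dtype=int)
            for i in range(self.minutes.shape[0]):
                row = self.minutes[i]
                order[i] = sorted(range(row.size), key=lambda j: (row[j], keys[j]))
            self._dest_order = order
        return self._dest_order

    def to_frame(self) -> pd.DataFrame:
        """Long-form (origin, destination, minutes) table."""
        recs = []
        for i, o in enumerate(self.origin_ids):
            for j, d in enumerate(self.destination_ids):
                recs.append((o, d, self.minutes[i, j]))
        return pd.DataFrame(recs, columns=["origin", "destination", "minutes"])


def travel_matrix(network, origins: Mapping, destinations: Mapping) -> TravelMatrix:
    """Exact shortest-path minutes from every origin to every destination.

    ``origins`` and ``destinations`` map an identifier to the network
    node the point is snapped to.  Dijkstra runs once per distinct
    origin node; no heuristics.
    """
    if not origins:
        raise ValueError("origins must be non-empty")
    if not destinations:
        raise ValueError("destinations must be non-empty")
    graph = network.graph()
    origin_ids = list(origins)
    dest_ids = list(destinations)
    dest_nodes = [destinations[d] for d in dest_ids]
    minutes = np.full((len(origin_ids), len(dest_ids)), UNREACHABLE)
    by_node: dict[int, dict] = {}
    for i, oid in enumerate(origin_ids):
        node = origins[oid]
        if node not in by_node:
            by_node[node] = nx.single_source_dijkstra_path_length(
                graph, node, weight="minutes")
        dist = by_node[node]
        for j, dnode in enumerate(dest_nodes):
            minutes[i, j] = dist.get(dnode, UNREACHABLE)
    return TravelMatrix(origin_ids, dest_ids, minutes)


@dataclass(frozen=True)
class CatchmentClassification:
    """Band membership plus nearest site for every tract."""

    bands: tuple
    band_of: Mapping[str, str]
    min_minutes: Mapping[str, float]
    nearest_site: Mapping[str, object]

    def band_labels(self) -> list[str]:
        return [f"within_{int(b)}" for b in self.bands] + [f"over_{int(self.bands[-1])}"]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"tract_id": t, "band": self.band_of[t],
             "min_minutes": self.min_minutes[t],
             "nearest_site": self.nearest_site[t]}
            for t in self.band_of
        ]
        return pd.DataFrame(rows)


def classify_catchment(matrix: TravelMatrix, bands: Sequence[float] = (15.0, 30.0)
                       ) -> CatchmentClassification:
    """Assign each origin tract a band from its minimum drive time.

    Band edges are closed on the right: minimum time t* falls in
    ``within_b`` for the smallest band edge b with t* <= b, and in
    ``over_<last>`` otherwise (including unreachable).
    """
    if len(matrix.destination_ids) < 1:
        raise ValueError("matrix must have at least one destination")
    bands = tuple(sorted(float(b) for b in bands))
    band_of, min_minutes, nearest = {}, {}, {}
    dest_keys = [str(d) for d in matrix.destination_ids]
    for i, tract in enumerate(matrix.origin_ids):
        row = matrix.minutes[i]
        j = min(range(row.size), key=lambda k: (row[k], dest_keys[k]))
        t_star = row[j]
        label = f"over_{int(bands[-1])}"
        for b in bands:
            if t_star <= b:
                label = f"within_{int(b)}"
                break
        band_of[tract] = label
        min_minutes[tract] = float(t_star)
        nearest[tract] = matrix.destination_ids[j] if math.isfinite(t_star) else None
    return CatchmentClassification(bands, band_of, min_minutes, nearest)


def catchment_summary(classification: CatchmentClassification, tracts: Iterable
                      ) -> pd.DataFrame:
    """Percent of tracts per band, by county and statewide.

    Percentages are unrounded; they sum to 100 per row exactly.
    """
    county_of = {t.tract_id: t.county for t in tracts}
    missing = set(county_of) - set(classification.band_of)
    if missing:
        raise ValueError(f"unclassified tracts: {sorted(missing)[:5]}")
    labels = classification.band_labels()
    frame = pd.DataFrame({
        "tract_id": list(county_of),
        "county": [county_of[t] for t in county_of],
        "band": [classification.band_of[t] for t in county_of],
    })
    rows = []
    groups = [("statewide", frame)] + [
        (county, sub) for county, sub in frame.groupby("county", sort=True)
    ]
    for name, sub in groups:
        counts = sub["band"].value_counts()
        n = len(sub)
        row = {"county": name, "n_tracts": n}
        for label in labels:
            row[f"pct_{label}"] = 100.0 * counts.get(label, 0) / n
        rows.append(row)
    return pd.DataFrame(rows)
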