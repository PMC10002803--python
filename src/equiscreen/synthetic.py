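"""Seeded synthetic study regions: tracts, blocks, facilities, roads.

The generator emulates the structure the downstream analysis assumes
without any external data: one urban county (more tracts, younger,
more Black women, fewer vehicles, more bus stops) stacked above a
larger rural area, a jittered-lattice road network (dense and slow in
the urban band, sparse and fast elsewhere) repaired to a single
connected component, and a facility inventory concentrated where
people live, with BICOE designation far more common in the urban
county.

Coordinates are planar kilometres; travel time depends only on edge
lengths and speeds, so no projection machinery is needed.  All
randomness flows from ``ScenarioConfig.seed`` through one generator,
making scenarios bit-identical for a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .demand import PER_UNIT_ANNUAL, facility_capacity
from .regression import COVARIATE_ORDER

__all__ = [
    "PopulationBlock",
    "Tract",
    "Facility",
    "RoadNetwork",
    "ScenarioConfig",
    "PlantedCounts",
    "generate_scenario",
    "weighted_centroid",
    "plant_known_rates",
]


@dataclass(frozen=True)
class PopulationBlock:
    block_id: str
    tract_id: str
    x: float
    y: float
    population: int

    def __post_init__(self):
        if self.population < 0:
            raise ValueError("block population must be non-negative")


@dataclass(frozen=True)
class Tract:
    """Census-tract-like demand unit with demographics and a centroid."""

    tract_id: str
    county: str                 # "urban" | "rural"
    population: int
    women_40_49: int
    women_50_74: int
    women_over_74: int
    pct_black_women: float
    deprivation: float
    pct_vehicle: float
    bus_stops: int
    centroid_x: float
    centroid_y: float
    node_id: int | None = None  # snapped road-network node

    def __post_init__(self):
        if self.population <= 0:
            raise ValueError(f"tract {self.tract_id} must be populated")
        women = self.women_40_49 + self.women_50_74 + self.women_over_74
        if women > self.population:
            raise ValueError(f"tract {self.tract_id}: women counts exceed population")
        for name in ("pct_black_women", "pct_vehicle"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"tract {self.tract_id}: {name}={v} outside [0,1]")


@dataclass(frozen=True)
class Facility:
    """Mammography site with unit count, capacity and quality flag."""

    facility_id: str
    x: float
    y: float
    units: int
    bicoe: bool
    capacity: float
    county: str | None = None
    tract_id: str | None = None
    node_id: int | None = None

    def __post_init__(self):
        if self.units < 1:
            raise ValueError("facility must have at least one unit")
        expected = facility_capacity(self.units)
        if not math.isclose(self.capacity, expected):
            raise ValueError(
                f"facility {self.facility_id}: capacity {self.capacity} != "
                f"units x per-unit capacity {expected}")


@dataclass
class RoadNetwork:
    """Undirected road network: nodes with coordinates, weighted edges."""

    nodes: list            # (node_id, x, y)
    edges: list            # (node_a, node_b, length_km, speed_kmh)
    _graph: nx.Graph | None = field(default=None, repr=False)
    _xy: np.ndarray | None = field(default=None, repr=False)
    _ids: np.ndarray | None = field(default=None, repr=False)

    def graph(self) -> nx.Graph:
        """networkx view with a ``minutes`` weight per edge (cached)."""
        if self._graph is None:
            g = nx.Graph()
            for nid, x, y in self.nodes:
                g.add_node(nid, x=x, y=y)
            for a, b, length, speed in self.edges:
                if length <= 0 or speed <= 0:
                    raise ValueError("edges must have positive length and speed")
                g.add_edge(a, b, length_km=length, speed_kmh=speed,
                           minutes=60.0 * length / speed)
            self._graph = g
        return self._graph

    def snap(self, x: float, y: float) -> int:
        """Nearest node by Euclidean distance; ties -> smallest node id."""
        if self._xy is None:
            order = sorted(self.nodes, key=lambda n: n[0])
            self._ids = np.array([n[0] for n in order])
            self._xy = np.array([[n[1], n[2]] for n in order])
        d2 = (self._xy[:, 0] - x) ** 2 + (self._xy[:, 1] - y) ** 2
        return int(self._ids[int(np.argmin(d2))])  # argmin keeps first = smallest id


@dataclass
class ScenarioConfig:
    """All knobs of the synthetic region, with urban/rural contrasts.

    Defaults are shaped so ~214 tracts split 129 urban / 85 rural,
    ~30 facilities carry ~1.5 units each, and roughly 30% of sites are
    BICOE with a heavy urban skew.
    """

    seed: int = 17
    n_tracts_urban: int = 129
    n_tracts_rural: int = 85
    blocks_per_tract: int = 5
    # geometry: the urban county is the top band of a tall rectangle
    width_km: float = 50.0
    height_km: float = 150.0
    urban_height_km: float = 30.0
    # rural settlement structure: tracts cluster around towns, with a
    # remote fraction scattered uniformly (these drive the >30 min tail)
    n_rural_towns: int = 5
    rural_town_sd_km: float = 5.0
    rural_remote_frac: float = 0.22
    remote_facility_weight: float = 0.05
    # demographics
    mean_population_urban: float = 4300.0
    mean_population_rural: float = 4570.0
    women_40_49_frac_urban: float = 0.066
    women_40_49_frac_rural: float = 0.058
    women_50_74_frac_urban: float = 0.151
    women_50_74_frac_rural: float = 0.180
    women_over_74_frac_urban: float = 0.036
    women_over_74_frac_rural: float = 0.046
    pct_black_mean_urban: float = 0.26
    pct_black_mean_rural: float = 0.16
    pct_black_conc: float = 3.0
    pct_vehicle_mean_urban: float = 0.91
    pct_vehicle_mean_rural: float = 0.95
    pct_vehicle_conc: float = 60.0
    bus_stops_mean_urban: float = 14.0
    bus_stops_mean_rural: float = 7.0
    # facilities
    n_facilities: int = 30
    urban_facility_share: float = 0.53
    unit_probs: Sequence[float] = (0.65, 0.25, 0.07, 0.03)  # P(units = 1..4)
    bicoe_prob_urban: float = 0.44
    bicoe_prob_rural: float = 0.14
    # road network
    urban_spacing_km: float = 2.0
    rural_spacing_km: float = 5.0
    urban_speed_kmh: float = 50.0
    rural_speed_kmh: float = 65.0
    jitter_frac: float = 0.3

    def validate(self) -> None:
        if self.n_tracts_urban < 1 or self.n_tracts_rural < 1:
            raise ValueError("each county needs at least one tract")
        if self.blocks_per_tract < 1:
            raise ValueError("blocks_per_tract must be positive")
        if self.n_facilities < 1:
            raise ValueError("need at least one facility")
        if not 0.0 < self.urban_height_km < self.height_km:
            raise ValueError("urban band must lie inside the region")
        if abs(sum(self.unit_probs) - 1.0) > 1e-9:
            raise ValueError("unit_probs must sum to 1")
        for name in ("urban_facility_share", "bicoe_prob_urban", "bicoe_prob_rural",
                     "pct_black_mean_urban", "pct_black_mean_rural",
                     "pct_vehicle_mean_urban", "pct_vehicle_mean_rural"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("urban_spacing_km", "rural_spacing_km",
                     "urban_speed_kmh", "rural_speed_kmh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioConfig":
        data = json.loads(text)
        data["unit_probs"] = tuple(data.get("unit_probs", cls.unit_probs))
        return cls(**data)


def weighted_centroid(blocks: Sequence) -> tuple[float, float]:
    """Population-weighted mean coordinate of a tract's blocks."""
    blocks = list(blocks)
    if not blocks:
        raise ValueError("need at least one block")
    total = float(sum(b.population for b in blocks))
    if total <= 0:
        raise ValueError("centroid undefined: total block population is zero")
    x = sum(b.population * b.x for b in blocks) / total
    y = sum(b.population * b.y for b in blocks) / total
    return (x, y)


# --------------------------------------------------------------------------
# scenario generation


def _lattice(rng, x0, y0, x1, y1, spacing, speed, jitter_frac, start_id):
    """Jittered rectangular lattice over [x0,x1] x [y0,y1]."""
    nx_ = max(2, int(round((x1 - x0) / spacing)))
    ny_ = max(2, int(round((y1 - y0) / spacing)))
    dx, dy = (x1 - x0) / nx_, (y1 - y0) / ny_
    nodes, index = [], {}
    nid = start_id
    for iy in range(ny_):
        for ix in range(nx_):
            jx = rng.uniform(-jitter_frac, jitter_frac) * dx / 2
            jy = rng.uniform(-jitter_frac, jitter_frac) * dy / 2
            x = x0 + (ix + 0.5) * dx + jx
            y = y0 + (iy + 0.5) * dy + jy
            nodes.append((nid, x, y))
            index[(ix, iy)] = nid
            nid += 1
    xy = {n[0]: (n[1], n[2]) for n in nodes}
    edges = []
    for (ix, iy), a in index.items():
        for nb in ((ix + 1, iy), (ix, iy + 1)):
            if nb in index:
                b = index[nb]
                ax, ay = xy[a]
                bx, by = xy[b]
                length = math.hypot(bx - ax, by - ay)
                edges.append((a, b, length, speed))
    return nodes, edges, nid


def _repair_connectivity(nodes, edges, speed):
    """Join components with their closest node pair until connected."""
    g = nx.Graph()
    g.add_nodes_from(n[0] for n in nodes)
    g.add_edges_from((a, b) for a, b, _, _ in edges)
    xy = {n[0]: (n[1], n[2]) for n in nodes}
    extra = []
    while True:
        comps = sorted(nx.connected_components(g), key=lambda c: min(c))
        if len(comps) == 1:
            break
        first, rest = comps[0], set().union(*comps[1:])
        best = None
        for a in sorted(first):
            for b in sorted(rest):
                d = math.hypot(xy[b][0] - xy[a][0], xy[b][1] - xy[a][1])
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        extra.append((a, b, max(d, 1e-6), speed))
        g.add_edge(a, b)
    return edges + extra


def _build_network(cfg: ScenarioConfig, rng) -> RoadNetwork:
    y_split = cfg.height_km - cfg.urban_height_km
    u_nodes, u_edges, nid = _lattice(
        rng, 0, y_split, cfg.width_km, cfg.height_km,
        cfg.urban_spacing_km, cfg.urban_speed_kmh, cfg.jitter_frac, 0)
    r_nodes, r_edges, _ = _lattice(
        rng, 0, 0, cfg.width_km, y_split,
        cfg.rural_spacing_km, cfg.rural_speed_kmh, cfg.jitter_frac, nid)
    nodes = u_nodes + r_nodes
    edges = _repair_connectivity(nodes, u_edges + r_edges, cfg.rural_speed_kmh)
    return RoadNetwork(nodes=nodes, edges=edges)


def _beta_params(mean, conc):
    return mean * conc, (1.0 - mean) * conc


def _draw_county_tracts(cfg, rng, network, county, n, y_lo, y_hi, start):
    """Returns (tracts, blocks, host_weight_multipliers).

    Rural tracts cluster around town centers; a remote fraction is
    scattered uniformly and carries a much smaller facility-hosting
    weight, producing the long-drive rural tail.
    """
    tracts, blocks, host_mult = [], [], []
    towns = None
    if county == "rural" and cfg.n_rural_towns > 0:
        towns = np.column_stack([
            rng.uniform(0.1 * cfg.width_km, 0.9 * cfg.width_km, cfg.n_rural_towns),
            rng.uniform(y_lo + 0.05 * (y_hi - y_lo), y_hi - 0.05 * (y_hi - y_lo),
                        cfg.n_rural_towns),
        ])
    if county == "urban":
        mean_pop = cfg.mean_population_urban
        fracs = (cfg.women_40_49_frac_urban, cfg.women_50_74_frac_urban,
                 cfg.women_over_74_frac_urban)
        black_mean, vehicle_mean = cfg.pct_black_mean_urban, cfg.pct_vehicle_mean_urban
        bus_mean = cfg.bus_stops_mean_urban
    else:
        mean_pop = cfg.mean_population_rural
        fracs = (cfg.women_40_49_frac_rural, cfg.women_50_74_frac_rural,
                 cfg.women_over_74_frac_rural)
        black_mean, vehicle_mean = cfg.pct_black_mean_rural, cfg.pct_vehicle_mean_rural
        bus_mean = cfg.bus_stops_mean_rural
    for k in range(n):
        tid = f"T{start + k:04d}"
        remote = False
        if towns is not None:
            remote = bool(rng.random() < cfg.rural_remote_frac)
            if remote:
                seed_x = rng.uniform(0.0, cfg.width_km)
                seed_y = rng.uniform(y_lo, y_hi)
            else:
                tx, ty = towns[int(rng.integers(len(towns)))]
                seed_x = float(np.clip(rng.normal(tx, cfg.rural_town_sd_km),
                                       0.0, cfg.width_km))
                seed_y = float(np.clip(rng.normal(ty, cfg.rural_town_sd_km),
                                       y_lo, y_hi))
        else:
            seed_x = rng.uniform(0.0, cfg.width_km)
            seed_y = rng.uniform(y_lo, y_hi)
        pop_mean = mean_pop * (0.6 if remote else 1.0)
        population = max(200, int(rng.gamma(11.0, pop_mean / 11.0)))
        women = []
        for frac in fracs:
            f = float(np.clip(rng.normal(frac, 0.25 * frac), 0.002, 0.45))
            women.append(int(rng.binomial(population, f)))
        if sum(women) > population:  # extremely rare; rescale proportionally
            scale = population / sum(women)
            women = [int(w * scale) for w in women]
        a, b = _beta_params(black_mean, cfg.pct_black_conc)
        pct_black = float(rng.beta(a, b))
        a, b = _beta_params(vehicle_mean, cfg.pct_vehicle_conc)
        pct_vehicle = float(rng.beta(a, b))
        deprivation = float(rng.normal(0.0, 1.0))
        bus_stops = int(rng.poisson(bus_mean))
        # blocks: scatter around the tract seed, integer multinomial split
        k_blocks = cfg.blocks_per_tract
        bx = np.clip(seed_x + rng.normal(0, 1.5, k_blocks), 0.0, cfg.width_km)
        by = np.clip(seed_y + rng.normal(0, 1.5, k_blocks), y_lo, y_hi)
        shares = rng.dirichlet(np.ones(k_blocks))
        pops = rng.multinomial(population, shares)
        tract_blocks = [
            PopulationBlock(block_id=f"{tid}B{j}", tract_id=tid,
                            x=float(bx[j]), y=float(by[j]), population=int(pops[j]))
            for j in range(k_blocks)
        ]
        cx, cy = weighted_centroid(tract_blocks)
        tracts.append(Tract(
            tract_id=tid, county=county, population=population,
            women_40_49=women[0], women_50_74=women[1], women_over_74=women[2],
            pct_black_women=pct_black, deprivation=deprivation,
            pct_vehicle=pct_vehicle, bus_stops=bus_stops,
            centroid_x=cx, centroid_y=cy, node_id=network.snap(cx, cy)))
        blocks.extend(tract_blocks)
        host_mult.append(cfg.remote_facility_weight if remote else 1.0)
    return tracts, blocks, host_mult


def _draw_facilities(cfg, rng, tracts, host_mult, network):
    by_county = {"urban": [(t, m) for t, m in zip(tracts, host_mult)
                           if t.county == "urban"],
                 "rural": [(t, m) for t, m in zip(tracts, host_mult)
                           if t.county == "rural"]}
    n_urban = int(round(cfg.n_facilities * cfg.urban_facility_share))
    n_urban = min(n_urban, len(by_county["urban"]))
    plan = [("urban", n_urban, cfg.bicoe_prob_urban),
            ("rural", cfg.n_facilities - n_urban, cfg.bicoe_prob_rural)]
    facilities = []
    fid = 0
    for county, n, bicoe_prob in plan:
        pool = [t for t, _ in by_county[county]]
        n = min(n, len(pool))
        weights = np.array([t.population * m for t, m in by_county[county]],
                           dtype=float)
        hosts = rng.choice(len(pool), size=n, replace=False, p=weights / weights.sum())
        for i in sorted(int(h) for h in hosts):
            host = pool[i]
            x = float(host.centroid_x + rng.normal(0, 0.5))
            y = float(host.centroid_y + rng.normal(0, 0.5))
            units = int(rng.choice(np.arange(1, len(cfg.unit_probs) + 1),
                                   p=np.asarray(cfg.unit_probs)))
            bicoe = bool(rng.random() < bicoe_prob)
            facilities.append(Facility(
                facility_id=f"F{fid:03d}", x=x, y=y, units=units, bicoe=bicoe,
                capacity=facility_capacity(units), county=county,
                tract_id=host.tract_id, node_id=network.snap(x, y)))
            fid += 1
    return facilities


def generate_scenario(config: ScenarioConfig):
    """Generate (tracts, blocks, facilities, network) from one seed.

    Deterministic: the same config yields byte-identical output.  The
    urban county sits in the top band of the region; drawing order is
    fixed (network, urban tracts, rural tracts, facilities) so adding
    draws to one stage never perturbs another retroactively.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    network = _build_network(config, rng)
    y_split = config.height_km - config.urban_height_km
    urban, u_blocks, u_mult = _draw_county_tracts(
        config, rng, network, "urban", config.n_tracts_urban,
        y_split, config.height_km, 0)
    rural, r_blocks, r_mult = _draw_county_tracts(
        config, rng, network, "rural", config.n_tracts_rural,
        0.0, y_split, config.n_tracts_urban)
    tracts = urban + rural
    facilities = _draw_facilities(config, rng, tracts, u_mult + r_mult, network)
    return tracts, u_blocks + r_blocks, facilities, network


# --------------------------------------------------------------------------
# planted-rate count generation for regression recovery


@dataclass(frozen=True)
class PlantedCounts:
    """Counts drawn from a known log-linear rate with population offset."""

    counts: np.ndarray
    expected: np.ndarray
    intercept: float
    coefficients: Mapping[str, float]
    scaling: Mapping[str, tuple]


def plant_known_rates(tracts: Sequence, true_coefficients, seed: int,
                      intercept: float = -8.0) -> PlantedCounts:
    """Draw per-tract Poisson counts with a known linear predictor.

    The log rate is ``intercept + sum_k beta_k * z_k + log(population)``
    where each covariate is standardized (sample SD) across the given
    tracts; the constants used are returned so a fit can be compared
    on the same scale.  ``true_coefficients`` is either a mapping from
    covariate name to beta (missing names get 0) or a sequence in
    ``COVARIATE_ORDER``.
    """
    if isinstance(true_coefficients, Mapping):
        beta = {name: float(true_coefficients.get(name, 0.0))
                for name in COVARIATE_ORDER}
        unknown = set(true_coefficients) - set(COVARIATE_ORDER)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")
    else:
        vals = list(true_coefficients)
        if len(vals) != len(COVARIATE_ORDER):
            raise ValueError(
                f"expected {len(COVARIATE_ORDER)} coefficients, got {len(vals)}")
        beta = dict(zip(COVARIATE_ORDER, (float(v) for v in vals)))
    tracts = list(tracts)
    pop = np.array([t.population for t in tracts], dtype=float)
    if np.any(pop <= 0):
        raise ValueError("tracts must have positive population")
    eta = np.full(len(tracts), float(intercept))
    scaling = {}
    for name in COVARIATE_ORDER:
        raw = np.array([getattr(t, name) for t in tracts], dtype=float)
        mean, sd = float(raw.mean()), float(raw.std(ddof=1))
        if sd == 0.0:
            if beta[name] != 0.0:
                raise ValueError(f"covariate {name!r} is constant")
            scaling[name] = (mean, sd)
            continue
        eta += beta[name] * (raw - mean) / sd
        scaling[name] = (mean, sd)
    eta += np.log(pop)
    with np.errstate(over="ignore"):
        mu = np.exp(eta)
    if not np.all(np.isfinite(mu)):
        raise ValueError("non-finite rates; check coefficients and intercept")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mu)
    return PlantedCounts(counts=counts, expected=mu, intercept=float(intercept),
                         coefficients=beta, scaling=scaling)
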