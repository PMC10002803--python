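import numpy as np
import pytest

from equiscreen.allocation import AllocationProblem, DemandPoint, Site
from equiscreen.synthetic import RoadNetwork, ScenarioConfig, Tract, generate_scenario
from equiscreen.travel import TravelMatrix


def make_tract(tract_id="T0001", county="urban", population=5000,
               women_40_49=300, women_50_74=700, women_over_74=150,
               pct_black_women=0.2, deprivation=0.0, pct_vehicle=0.9,
               bus_stops=10, centroid_x=1.0, centroid_y=1.0, node_id=None):
    return Tract(tract_id=tract_id, county=county, population=population,
                 women_40_49=women_40_49, women_50_74=women_50_74,
                 women_over_74=women_over_74, pct_black_women=pct_black_women,
                 deprivation=deprivation, pct_vehicle=pct_vehicle,
                 bus_stops=bus_stops, centroid_x=centroid_x,
                 centroid_y=centroid_y, node_id=node_id)


def line_network(n=3, spacing_km=10.0, speed_kmh=40.0):
    """n nodes on a line, consecutive nodes joined."""
    nodes = [(i, i * spacing_km, 0.0) for i in range(n)]
    edges = [(i, i + 1, spacing_km, speed_kmh) for i in range(n - 1)]
    return RoadNetwork(nodes=nodes, edges=edges)


def random_cmclp_instance(seed, n_candidates=8, max_p=3):
    """Small random capacitated-coverage instance for oracle tests."""
    rng = np.random.default_rng(seed)
    n_dem = int(rng.integers(20, 61))
    n_req = int(rng.integers(0, 3))
    p = int(rng.integers(1, max_p + 1))
    dem_ids = [f"T{i:02d}" for i in range(n_dem)]
    required = [Site(f"R{i}", float(rng.uniform(200, 600))) for i in range(n_req)]
    candidates = [Site(f"C{i}", float(rng.uniform(100, 400)))
                  for i in range(n_candidates)]
    all_ids = [s.site_id for s in required + candidates]
    minutes = rng.uniform(0, 40, size=(n_dem, len(all_ids)))
    matrix = TravelMatrix(dem_ids, all_ids, minutes)
    points = [DemandPoint(t, float(rng.uniform(10, 100))) for t in dem_ids]
    return AllocationProblem(demand_points=points, required_sites=required,
                             candidates=candidates, p=p, matrix=matrix,
                             cutoff_minutes=20.0)


@pytest.fixture(scope="session")
def small_config():
    return ScenarioConfig(seed=7, n_tracts_urban=12, n_tracts_rural=8,
                          n_facilities=6, width_km=30.0, height_km=60.0,
                          urban_height_km=20.0, urban_spacing_km=4.0,
                          rural_spacing_km=8.0)


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return generate_scenario(small_config)


@pytest.fixture(scope="session")
def default_scenario():
    return generate_scenario(ScenarioConfig())
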