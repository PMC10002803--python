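import itertools

import numpy as np
import pytest

from equiscreen.allocation import (AllocationProblem, DemandPoint, Site,
                                   assign_demand, bicoe_conversion,
                                   cumulative_siting, default_cell_km,
                                   drive_time_improvement, fishnet_candidates,
                                   solve_cmclp)
from equiscreen.synthetic import Facility
from equiscreen.travel import TravelMatrix

from conftest import line_network, random_cmclp_instance


def matrix_of(minutes, origins=None, dests=None):
    minutes = np.asarray(minutes, dtype=float)
    origins = origins or [f"T{i}" for i in range(minutes.shape[0])]
    dests = dests or [f"S{j}" for j in range(minutes.shape[1])]
    return TravelMatrix(origins, dests, minutes)


class TestFishnet:
    def test_grid_count(self):
        cands = fishnet_candidates((0, 0, 10, 10), 5.0, network=None)
        assert len(cands) == 4
        assert {(c.x, c.y) for c in cands} == {(2.5, 2.5), (7.5, 2.5),
                                               (2.5, 7.5), (7.5, 7.5)}

    def test_snap_dedup(self):
        net = line_network(n=2, spacing_km=100)  # every cell snaps to node 0 or 1
        cands = fishnet_candidates((0, -5, 20, 5), 5.0, net)
        assert len(cands) < 8
        assert len({c.node_id for c in cands}) == len(cands)

    def test_degenerate_cell_larger_than_extent(self):
        cands = fishnet_candidates((0, 0, 10, 10), 15.0, network=None)
        assert len(cands) == 1
        assert (cands[0].x, cands[0].y) == (5.0, 5.0)

    def test_capacity_is_one_unit(self):
        c = fishnet_candidates((0, 0, 10, 10), 5.0, network=None)[0]
        assert c.units == 1 and c.capacity == 4500

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            fishnet_candidates((0, 0, 10, 10), 0, None)
        with pytest.raises(ValueError, match="degenerate"):
            fishnet_candidates((0, 0, 0, 10), 5, None)

    def test_default_cell_targets_ratio(self):
        cell = default_cell_km((0, 0, 50, 150), 30)
        n = len(fishnet_candidates((0, 0, 50, 150), cell, network=None))
        assert 200 <= n <= 400  # ~10x the 30 existing sites


class TestAssignDemand:
    def test_feasible_singleton(self):
        m = matrix_of([[10.0]])
        a = assign_demand([Site("S0", 100)], [DemandPoint("T0", 50)], m, 20)
        assert a.assigned == {"T0": "S0"}
        assert a.loads["S0"] == 50
        assert a.covered_demand == 50

    def test_cutoff_binds(self):
        m = matrix_of([[25.0]])
        a = assign_demand([Site("S0", 100)], [DemandPoint("T0", 50)], m, 20)
        assert a.assigned == {}
        assert a.unassigned == ("T0",)

    def test_whole_point_capacity_binding(self):
        m = matrix_of([[5.0], [10.0]])
        a = assign_demand([Site("S0", 100)],
                          [DemandPoint("T0", 60), DemandPoint("T1", 60)], m, 20)
        assert a.assigned == {"T0": "S0"}
        assert "T1" in a.unassigned

    def test_nearer_point_gets_priority(self):
        m = matrix_of([[10.0], [5.0]])
        a = assign_demand([Site("S0", 60)],
                          [DemandPoint("T0", 60), DemandPoint("T1", 60)], m, 20)
        assert a.assigned == {"T1": "S0"}

    def test_loads_never_exceed_capacity(self):
        for seed in range(20):
            prob = random_cmclp_instance(seed)
            sites = list(prob.required_sites) + list(prob.candidates)
            a = assign_demand(sites, prob.demand_points, prob.matrix, 20)
            caps = {s.site_id: s.capacity for s in sites}
            for sid, load in a.loads.items():
                assert load <= caps[sid] + 1e-9

    def test_assigned_within_cutoff(self):
        prob = random_cmclp_instance(1)
        sites = list(prob.required_sites) + list(prob.candidates)
        a = assign_demand(sites, prob.demand_points, prob.matrix, 20)
        for tract, sid in a.assigned.items():
            assert prob.matrix.time(tract, sid) <= 20

    def test_site_id_tiebreak(self):
        m = matrix_of([[5.0, 5.0]], dests=["S1", "S0"])
        a = assign_demand([Site("S1", 100), Site("S0", 100)],
                          [DemandPoint("T0", 10)], m, 20)
        assert a.assigned["T0"] == "S0"

    def test_missing_site_rejected(self):
        m = matrix_of([[5.0]])
        with pytest.raises(ValueError, match="missing"):
            assign_demand([Site("ghost", 10)], [DemandPoint("T0", 1)], m, 20)


class TestSolveCmclp:
    def test_greedy_dominance(self):
        # one candidate reaches 1000 of uncovered demand, the other 400
        m = matrix_of([[5.0, 50.0], [50.0, 5.0]], origins=["T0", "T1"],
                      dests=["C0", "C1"])
        prob = AllocationProblem(
            demand_points=[DemandPoint("T0", 1000), DemandPoint("T1", 400)],
            required_sites=[], candidates=[Site("C0", 2000), Site("C1", 2000)],
            p=1, matrix=m)
        res = solve_cmclp(prob)
        assert res.opened == ("C0",)
        assert res.covered_demand == 1000

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce(self, seed):
        prob = random_cmclp_instance(seed)
        res = solve_cmclp(prob)
        best = max(
            assign_demand(list(prob.required_sites) + list(subset),
                          prob.demand_points, prob.matrix,
                          prob.cutoff_minutes).covered_demand
            for subset in itertools.combinations(prob.candidates, prob.p))
        assert res.covered_demand == pytest.approx(best)

    def test_saturated_baseline_zero_marginal(self):
        m = matrix_of([[2.0, 3.0, 4.0]], dests=["R0", "C0", "C1"])
        prob = AllocationProblem(
            demand_points=[DemandPoint("T0", 100)],
            required_sites=[Site("R0", 1000)],
            candidates=[Site("C0", 4500), Site("C1", 4500)], p=1, matrix=m)
        res = solve_cmclp(prob)
        assert res.marginal_coverage == 0
        assert res.zero_marginal

    def test_determinism(self):
        prob = random_cmclp_instance(3)
        assert solve_cmclp(prob).opened == solve_cmclp(prob).opened

    def test_p_exceeding_candidates_rejected(self):
        m = matrix_of([[1.0]], dests=["C0"])
        with pytest.raises(ValueError, match="exceeds"):
            AllocationProblem(demand_points=[DemandPoint("T0", 1)],
                              required_sites=[], candidates=[Site("C0", 10)],
                              p=2, matrix=m)

    def test_coverage_monotone_in_p(self):
        for seed in (0, 5, 9):
            prob = random_cmclp_instance(seed)
            prev = -1.0
            for p in range(1, min(4, len(prob.candidates)) + 1):
                import dataclasses
                res = solve_cmclp(dataclasses.replace(prob, p=p))
                assert res.covered_demand >= prev - 1e-9
                prev = res.covered_demand


class TestCumulativeSiting:
    def test_nesting(self):
        prob = random_cmclp_instance(2)
        import dataclasses
        prob = dataclasses.replace(prob, p=5)
        results = cumulative_siting(prob, (1, 3, 5))
        s1, s3, s5 = (set(results[p].opened) for p in (1, 3, 5))
        assert s1 <= s3 <= s5
        assert [len(s) for s in (s1, s3, s5)] == [1, 3, 5]

    def test_single_p_reduces_to_solve(self):
        prob = random_cmclp_instance(4)
        import dataclasses
        prob = dataclasses.replace(prob, p=1)
        assert cumulative_siting(prob, (1,))[1].opened == solve_cmclp(prob).opened

    def test_descending_p_rejected(self):
        prob = random_cmclp_instance(4)
        with pytest.raises(ValueError, match="ascending"):
            cumulative_siting(prob, (3, 1))


class TestDriveTimeImprovement:
    def test_identity(self):
        m = matrix_of([[10.0, 20.0]], dests=["A", "B"])
        sites = [Site("A", 10), Site("B", 10)]
        pct, by_county, mb, ma = drive_time_improvement(
            sites, sites, [DemandPoint("T0", 5)], m)
        assert pct == 0 and mb == ma

    def test_collapse_to_zero(self):
        m = matrix_of([[20.0, 0.0]], dests=["A", "B"])
        pct, _, mb, ma = drive_time_improvement(
            [Site("A", 10)], [Site("A", 10), Site("B", 10)],
            [DemandPoint("T0", 5)], m)
        assert pct == 100 and ma == 0

    def test_superset_required(self):
        m = matrix_of([[1.0, 2.0]], dests=["A", "B"])
        with pytest.raises(ValueError, match="superset"):
            drive_time_improvement([Site("A", 1)], [Site("B", 1)],
                                   [DemandPoint("T0", 1)], m)

    def test_by_county_split(self):
        m = matrix_of([[20.0, 0.0], [10.0, 10.0]], dests=["A", "B"])
        pct, by_county, _, _ = drive_time_improvement(
            [Site("A", 1)], [Site("A", 1), Site("B", 1)],
            [DemandPoint("T0", 5, county="u"), DemandPoint("T1", 5, county="r")],
            m)
        assert by_county["u"] == 100
        assert by_county["r"] == 0


def _facility(fid, units, bicoe, county="rural"):
    return Facility(facility_id=fid, x=0, y=0, units=units, bicoe=bicoe,
                    capacity=units * 4500.0, county=county)


class TestBicoeConversion:
    def test_single_candidate_forced(self):
        m = matrix_of([[5.0, 6.0]], dests=["B0", "N0"])
        facs = [_facility("B0", 1, True), _facility("N0", 1, False)]
        res = bicoe_conversion(facs, [DemandPoint("T0", 10)], m, p=1)
        assert res.opened == ("N0",)

    def test_no_bicoe_rejected(self):
        m = matrix_of([[5.0]], dests=["N0"])
        with pytest.raises(ValueError, match="BICOE"):
            bicoe_conversion([_facility("N0", 1, False)],
                             [DemandPoint("T0", 1)], m, p=1)

    def test_too_few_candidates_rejected(self):
        m = matrix_of([[5.0, 6.0]], dests=["B0", "N0"])
        facs = [_facility("B0", 1, True), _facility("N0", 1, False)]
        with pytest.raises(ValueError, match="non-BICOE"):
            bicoe_conversion(facs, [DemandPoint("T0", 1)], m, p=2)

    def test_saturated_flagged(self):
        # BICOE capacity covers everything; selection is deterministic filler
        m = matrix_of([[1.0, 1.0, 1.0]], dests=["B0", "N0", "N1"])
        facs = [_facility("B0", 2, True), _facility("N0", 1, False),
                _facility("N1", 1, False)]
        res = bicoe_conversion(facs, [DemandPoint("T0", 100)], m, p=1)
        assert res.zero_marginal
        assert res.opened == ("N0",)

    def test_candidates_keep_units_by_default(self):
        m = matrix_of([[30.0, 1.0]], dests=["B0", "N0"])
        facs = [_facility("B0", 1, True), _facility("N0", 2, False)]
        res = bicoe_conversion(facs, [DemandPoint("T0", 6000)], m, p=1)
        assert res.covered_demand == 6000  # needs the 9000 two-unit capacity
        res_single = bicoe_conversion(facs, [DemandPoint("T0", 6000)], m, p=1,
                                      single_unit=True)
        assert res_single.covered_demand == 0
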