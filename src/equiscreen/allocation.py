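"""Capacitated maximal-covering site selection with drive-time metrics.

Existing facilities are *required* (always open, capacity fixed);
candidates come from a regular fishnet grid snapped to the road
network, each with one unit of capacity by default.  The solver opens
exactly ``p`` candidates to maximize the demand assigned within a
drive-time cutoff without exceeding any site's capacity:

1. greedy construction — each step opens the candidate that adds the
   most covered demand given the required sites and previous picks;
2. pairwise interchange — swap one opened candidate for a closed one
   while covered demand strictly improves.

Demand is assigned whole-point: a tract's screenings go to the
nearest feasible site or nowhere.  All tie-breaks are total-ordered
(time, then site id, then tract id), so identical inputs give
identical solutions.  An exhaustive-enumeration oracle in the test
suite certifies optimality at small instance sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .demand import PER_UNIT_ANNUAL, facility_capacity
from .travel import TravelMatrix

__all__ = [
    "Site",
    "DemandPoint",
    "CandidateSite",
    "Assignment",
    "AllocationProblem",
    "AllocationResult",
    "fishnet_candidates",
    "default_cell_km",
    "assign_demand",
    "solve_cmclp",
    "cumulative_siting",
    "drive_time_improvement",
    "bicoe_conversion",
]


@dataclass(frozen=True)
class Site:
    """A service location with fixed annual capacity."""

    site_id: str
    capacity: float

    def __post_init__(self):
        if self.capacity < 0:
            raise ValueError("capacity must be non-negative")


@dataclass(frozen=True)
class CandidateSite(Site):
    """Grid-generated candidate, snapped to a network node."""

    x: float = 0.0
    y: float = 0.0
    units: int = 1
    node_id: int | None = None


@dataclass(frozen=True)
class DemandPoint:
    """Tract centroid with its annual screening weight."""

    tract_id: str
    weight: float
    county: str | None = None

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("demand weight must be non-negative")


@dataclass(frozen=True)
class Assignment:
    assigned: Mapping[str, str]       # tract_id -> site_id
    loads: Mapping[str, float]        # site_id -> assigned screenings
    covered_demand: float
    unassigned: tuple


@dataclass(frozen=True)
class AllocationProblem:
    demand_points: Sequence[DemandPoint]
    required_sites: Sequence[Site]
    candidates: Sequence[Site]
    p: int
    matrix: TravelMatrix
    cutoff_minutes: float = 20.0

    def __post_init__(self):
        if self.p > len(self.candidates):
            raise ValueError(
                f"p={self.p} exceeds candidate count {len(self.candidates)}")
        if self.cutoff_minutes <= 0:
            raise ValueError("cutoff must be positive")


@dataclass(frozen=True)
class AllocationResult:
    opened: tuple                     # candidate ids in selection order
    assignment: Assignment
    covered_demand: float
    baseline_covered: float
    marginal_coverage: float
    mean_min_drive_before: float
    mean_min_drive_after: float
    pct_drive_reduction: float
    pct_drive_reduction_by_county: Mapping[str, float]
    zero_marginal: bool = False


def default_cell_km(extent, n_existing_sites: int, target_ratio: float = 10.0) -> float:
    """Fishnet cell size giving ~``target_ratio`` candidates per existing site."""
    xmin, ymin, xmax, ymax = extent
    area = (xmax - xmin) * (ymax - ymin)
    m = max(1.0, target_ratio * max(1, n_existing_sites))
    return math.sqrt(area / m)


def fishnet_candidates(extent, cell_km: float, network, units: int = 1
                       ) -> list[CandidateSite]:
    """Regular-grid candidates over ``extent``, snapped to the network.

    The extent is partitioned into equal cells approximating
    ``cell_km``; each cell contributes its center, snapped to the
    nearest network node.  Cells snapping to the same node are merged,
    keeping the first in row-major order.  A cell larger than the
    extent degenerates to a single candidate at the extent center.
    """
    xmin, ymin, xmax, ymax = extent
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("extent is degenerate")
    nx_ = max(1, int((xmax - xmin) // cell_km))
    ny_ = max(1, int((ymax - ymin) // cell_km))
    dx, dy = (xmax - xmin) / nx_, (ymax - ymin) / ny_
    capacity = facility_capacity(units)
    out, seen = [], set()
    k = 0
    for iy in range(ny_):
        for ix in range(nx_):
            cx = xmin + (ix + 0.5) * dx
            cy = ymin + (iy + 0.5) * dy
            node = network.snap(cx, cy) if network is not None else None
            if node is not None and node in seen:
                continue
            seen.add(node)
            out.append(CandidateSite(site_id=f"C{k:04d}", capacity=capacity,
                                     x=cx, y=cy, units=units, node_id=node))
            k += 1
    if not out:
        raise ValueError("empty candidate grid")
    return out


def assign_demand(sites: Sequence[Site], demand_points: Sequence[DemandPoint],
                  matrix: TravelMatrix, cutoff: float) -> Assignment:
    """Greedy nearest-feasible whole-point assignment.

    Demand points are processed in ascending order of their
    nearest-site time (ties by tract id); each goes wholly to its
    nearest site with remaining capacity at most ``cutoff`` minutes
    away, or stays unassigned.
    """
    site_col = {}
    for s in sites:
        if s.site_id not in matrix._dcol:
            raise ValueError(f"site {s.site_id} missing from travel matrix")
        site_col[s.site_id] = matrix._dcol[s.site_id]
    active_cols = {site_col[s.site_id]: s.site_id for s in sites}
    remaining = {s.site_id: float(s.capacity) for s in sites}
    order_cache = matrix.sorted_destinations()

    cols = np.fromiter(active_cols.keys(), dtype=int)
    nearest = []
    for dp in demand_points:
        row = matrix.minutes[matrix._orow[dp.tract_id]]
        t = float(row[cols].min()) if cols.size else math.inf
        nearest.append((t, dp.tract_id, dp))
    nearest.sort(key=lambda r: (r[0], r[1]))

    assigned, unassigned = {}, []
    loads = {s.site_id: 0.0 for s in sites}
    for _, _, dp in nearest:
        i = matrix._orow[dp.tract_id]
        row = matrix.minutes[i]
        chosen = None
        for j in order_cache[i]:
            if j not in active_cols:
                continue
            t = row[j]
            if t > cutoff or not math.isfinite(t):
                break  # scan is ascending in time; nothing further is feasible
            sid = active_cols[j]
            if remaining[sid] >= dp.weight:
                chosen = sid
                break
        if chosen is None:
            unassigned.append(dp.tract_id)
        else:
            assigned[dp.tract_id] = chosen
            remaining[chosen] -= dp.weight
            loads[chosen] += dp.weight
    covered = float(sum(loads.values()))
    return Assignment(assigned=assigned, loads=loads, covered_demand=covered,
                      unassigned=tuple(unassigned))


def _coverage_fn(problem: AllocationProblem) -> Callable:
    """Memoized covered-demand evaluator over opened candidate id sets."""
    by_id = {c.site_id: c for c in problem.candidates}
    required = list(problem.required_sites)
    cache: dict[frozenset, float] = {}

    def coverage(open_ids: Iterable[str]) -> float:
        key = frozenset(open_ids)
        if key not in cache:
            sites = required + [by_id[c] for c in sorted(key)]
            cache[key] = assign_demand(sites, problem.demand_points,
                                       problem.matrix, problem.cutoff_minutes
                                       ).covered_demand
        return cache[key]

    return coverage


#: Pool size under which the interchange also explores two-site
#: exchanges; beyond it only single swaps are affordable.
PAIR_SWAP_POOL_LIMIT = 32


def _greedy_interchange(coverage: Callable, candidate_ids: Sequence[str],
                        p: int, frozen: Sequence[str] = ()) -> list[str]:
    """Greedy construction then interchange local search.

    Single open/closed swaps are applied best-improvement-first; when
    they stall and the closed pool is small (<= PAIR_SWAP_POOL_LIMIT),
    two-site exchanges are tried as well, which certifies optimality
    against exhaustive enumeration at oracle-test scale.  ``frozen``
    ids are kept open and never swapped out (used to nest solutions
    across increasing p).
    """
    opened = list(frozen)
    pool = sorted(c for c in candidate_ids if c not in set(frozen))
    while len(opened) < p:
        # ties on coverage break toward the smallest candidate id
        best = min(pool, key=lambda c: (-coverage(opened + [c]), c))
        opened.append(best)
        pool.remove(best)
    free = range(len(frozen), len(opened))
    improved = True
    while improved:
        improved = False
        best_cov = coverage(opened)
        best_move = None
        for k in free:
            for c in pool:
                trial = opened[:k] + [c] + opened[k + 1:]
                cov = coverage(trial)
                if cov > best_cov + 1e-9:
                    best_cov, best_move = cov, (trial, [opened[k]], [c])
        if best_move is None and len(free) >= 2 and len(pool) <= PAIR_SWAP_POOL_LIMIT:
            for k1, k2 in combinations(free, 2):
                for c1, c2 in combinations(pool, 2):
                    trial = list(opened)
                    trial[k1], trial[k2] = c1, c2
                    cov = coverage(trial)
                    if cov > best_cov + 1e-9:
                        best_cov = cov
                        best_move = (trial, [opened[k1], opened[k2]], [c1, c2])
        if best_move is not None:
            opened, out_ids, in_ids = best_move
            for o in out_ids:
                pool.append(o)
            for c in in_ids:
                pool.remove(c)
            pool.sort()
            improved = True
    return opened


def _min_drive(matrix: TravelMatrix, demand_points, site_ids) -> np.ndarray:
    sub = matrix.columns(list(site_ids))
    rows = [matrix._orow[dp.tract_id] for dp in demand_points]
    return sub[rows].min(axis=1) if sub.shape[1] else np.full(len(rows), math.inf)


def _drive_metrics(matrix, demand_points, before_ids, after_ids):
    before = _min_drive(matrix, demand_points, before_ids)
    after = _min_drive(matrix, demand_points, after_ids)
    w = np.array([dp.weight for dp in demand_points], dtype=float)
    finite = np.isfinite(before)
    w_f, b_f, a_f = w[finite], before[finite], after[finite]
    if w_f.sum() <= 0:
        return 0.0, 0.0, 0.0, {}
    mean_before = float(np.average(b_f, weights=w_f)) if w_f.size else 0.0
    mean_after = float(np.average(a_f, weights=w_f)) if w_f.size else 0.0
    overall = 0.0 if mean_before == 0 else 100.0 * (mean_before - mean_after) / mean_before
    by_county = {}
    counties = sorted({dp.county for dp in demand_points if dp.county is not None})
    for county in counties:
        mask = np.array([dp.county == county for dp in demand_points]) & finite
        if w[mask].sum() <= 0:
            by_county[county] = 0.0
            continue
        mb = float(np.average(before[mask], weights=w[mask]))
        ma = float(np.average(after[mask], weights=w[mask]))
        by_county[county] = 0.0 if mb == 0 else 100.0 * (mb - ma) / mb
    return mean_before, mean_after, overall, by_county


def drive_time_improvement(before_sites: Sequence[Site], after_sites: Sequence[Site],
                           demand_points: Sequence[DemandPoint],
                           matrix: TravelMatrix):
    """Demand-weighted percent reduction in minimum drive time.

    ``after_sites`` must contain every before site, so the reduction
    is never negative.  Returns (pct_overall, pct_by_county,
    mean_before, mean_after).
    """
    before_ids = [s.site_id for s in before_sites]
    after_ids = [s.site_id for s in after_sites]
    if not set(before_ids) <= set(after_ids):
        raise ValueError("after_sites must be a superset of before_sites")
    mb, ma, overall, by_county = _drive_metrics(
        matrix, demand_points, before_ids, after_ids)
    return overall, by_county, mb, ma


def _build_result(problem: AllocationProblem, opened: Sequence[str]
                  ) -> AllocationResult:
    by_id = {c.site_id: c for c in problem.candidates}
    required = list(problem.required_sites)
    open_sites = [by_id[c] for c in opened]
    final = assign_demand(required + open_sites, problem.demand_points,
                          problem.matrix, problem.cutoff_minutes)
    baseline = assign_demand(required, problem.demand_points,
                             problem.matrix, problem.cutoff_minutes)
    marginal = final.covered_demand - baseline.covered_demand
    req_ids = [s.site_id for s in required]
    mb, ma, overall, by_county = _drive_metrics(
        problem.matrix, problem.demand_points, req_ids, req_ids + list(opened))
    return AllocationResult(
        opened=tuple(opened),
        assignment=final,
        covered_demand=final.covered_demand,
        baseline_covered=baseline.covered_demand,
        marginal_coverage=marginal,
        mean_min_drive_before=mb,
        mean_min_drive_after=ma,
        pct_drive_reduction=overall,
        pct_drive_reduction_by_county=by_county,
        zero_marginal=bool(marginal <= 1e-9),
    )


def solve_cmclp(problem: AllocationProblem) -> AllocationResult:
    """Open exactly ``p`` candidates maximizing covered demand."""
    coverage = _coverage_fn(problem)
    ids = [c.site_id for c in problem.candidates]
    opened = _greedy_interchange(coverage, ids, problem.p)
    return _build_result(problem, opened)


def cumulative_siting(problem: AllocationProblem,
                      p_values: Sequence[int] = (1, 3, 5)
                      ) -> dict[int, AllocationResult]:
    """Nested solutions across increasing p.

    Sites chosen for a smaller p are retained verbatim in every larger
    solution; interchange only touches the newly added sites.
    """
    p_values = list(p_values)
    if p_values != sorted(p_values):
        raise ValueError("p_values must be ascending")
    if p_values and p_values[-1] > len(problem.candidates):
        raise ValueError("largest p exceeds candidate count")
    coverage = _coverage_fn(problem)
    ids = [c.site_id for c in problem.candidates]
    results: dict[int, AllocationResult] = {}
    fixed: list[str] = []
    for p in p_values:
        fixed = _greedy_interchange(coverage, ids, p, frozen=fixed)
        results[p] = _build_result(replace(problem, p=p), fixed)
    return results


def bicoe_conversion(facilities: Sequence, demand_points: Sequence[DemandPoint],
                     matrix: TravelMatrix, p: int = 5,
                     cutoff_minutes: float = 20.0,
                     single_unit: bool = False) -> AllocationResult:
    """Pick existing non-BICOE sites to convert to BICOE.

    BICOE sites keep their capacities as the required set; every
    non-BICOE facility becomes a candidate at its own location.  By
    default candidates keep their actual unit counts; ``single_unit``
    resets each to one unit's capacity.
    """
    bicoe = [f for f in facilities if f.bicoe]
    non_bicoe = [f for f in facilities if not f.bicoe]
    if not bicoe:
        raise ValueError("need at least one BICOE site")
    if len(non_bicoe) < p:
        raise ValueError(f"only {len(non_bicoe)} non-BICOE sites for p={p}")
    required = [Site(site_id=f.facility_id, capacity=f.capacity) for f in bicoe]
    candidates = [
        Site(site_id=f.facility_id,
             capacity=PER_UNIT_ANNUAL if single_unit else f.capacity)
        for f in non_bicoe
    ]
    problem = AllocationProblem(demand_points=demand_points,
                                required_sites=required, candidates=candidates,
                                p=p, matrix=matrix, cutoff_minutes=cutoff_minutes)
    return solve_cmclp(problem)
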