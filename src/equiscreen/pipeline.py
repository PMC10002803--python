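"""End-to-end run: simulate, catchment, demand, regress, allocate, report.

``run_pipeline`` writes every stage's output under one directory plus
a manifest holding the config, its hash, per-file content digests and
row counts.  Rerunning the same config reproduces identical file
content, so the manifest doubles as a reproducibility check.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__, io
from .allocation import (AllocationProblem, DemandPoint, bicoe_conversion,
                         cumulative_siting, default_cell_km, fishnet_candidates)
from .demand import SPEC_NAMES, demand_specification
from .regression import counts_by_tract, stratified_fits
from .report import inventory_summary
from .synthetic import ScenarioConfig, generate_scenario
from .travel import classify_catchment, catchment_summary, travel_matrix

logger = logging.getLogger("equiscreen")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    specs: Sequence[str] = SPEC_NAMES
    bands: Sequence[float] = (15.0, 30.0)
    cutoff_minutes: float = 20.0
    p_values: Sequence[int] = (1, 3, 5)
    cell_km: float | None = None      # None -> ~10 candidates per existing site
    bicoe_p: int = 5
    write_geojson: bool = False

    def validate(self) -> None:
        self.scenario.validate()
        unknown = set(self.specs) - set(SPEC_NAMES)
        if unknown:
            raise ValueError(f"unknown demand specs: {sorted(unknown)}")
        if list(self.p_values) != sorted(self.p_values):
            raise ValueError("p_values must be ascending")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        scenario = ScenarioConfig.from_json(json.dumps(data.pop("scenario", {})))
        cfg = cls(scenario=scenario, **{k: v for k, v in data.items()})
        cfg.specs = tuple(cfg.specs)
        cfg.bands = tuple(cfg.bands)
        cfg.p_values = tuple(cfg.p_values)
        return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _allocation_json(spec_name, results, cutoff):
    out = {"spec": spec_name, "cutoff_minutes": cutoff, "solutions": {}}
    for p, res in results.items():
        out["solutions"][str(p)] = {
            "opened": list(res.opened),
            "covered_demand": res.covered_demand,
            "baseline_covered": res.baseline_covered,
            "marginal_coverage": res.marginal_coverage,
            "mean_min_drive_before": res.mean_min_drive_before,
            "mean_min_drive_after": res.mean_min_drive_after,
            "pct_drive_reduction": res.pct_drive_reduction,
            "pct_drive_reduction_by_county": dict(res.pct_drive_reduction_by_county),
            "assignment": dict(sorted(res.assignment.assigned.items())),
            "unassigned": sorted(res.assignment.unassigned),
        }
    return out


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage, write outputs under ``out_dir``, return the manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": json.loads(config.to_json()),
                "seed": config.scenario.seed,
                "version": __version__,
                "config_sha256": hashlib.sha256(
                    config.to_json().encode()).hexdigest(),
                "stages": {}}

    def stage(name):
        logger.info("stage %s", name)
        return name

    try:
        stage("simulate")
        tracts, blocks, facilities, network = generate_scenario(config.scenario)
        io.write_tracts(tracts, out / "tracts.csv")
        io.write_blocks(blocks, out / "blocks.csv")
        io.write_facilities(facilities, out / "facilities.csv")
        io.write_network(network, out / "nodes.csv", out / "edges.csv")
        if config.write_geojson:
            io.write_geojson(io.scenario_geojson(tracts, facilities, network),
                             out / "scenario.geojson")
        manifest["stages"]["simulate"] = {
            "tracts": len(tracts), "blocks": len(blocks),
            "facilities": len(facilities), "nodes": len(network.nodes),
            "edges": len(network.edges)}
    except Exception as exc:
        raise PipelineError(f"simulate: {exc}") from exc

    try:
        stage("catchment")
        origins = {t.tract_id: t.node_id for t in tracts}
        fac_dest = {f.facility_id: f.node_id for f in facilities}
        fac_matrix = travel_matrix(network, origins, fac_dest)
        classification = classify_catchment(fac_matrix, config.bands)
        classification.to_frame().to_csv(out / "catchment.csv", index=False)
        catchment_summary(classification, tracts).to_csv(
            out / "catchment_summary.csv", index=False)
        manifest["stages"]["catchment"] = {"tracts": len(tracts)}
    except Exception as exc:
        raise PipelineError(f"catchment: {exc}") from exc

    try:
        stage("demand")
        spec_tables = {}
        for name in config.specs:
            spec = demand_specification(tracts, name)
            spec_tables[name] = spec
            spec.table.to_csv(out / f"demand_{name}.csv", index=False)
        manifest["stages"]["demand"] = {"specs": list(config.specs)}
    except Exception as exc:
        raise PipelineError(f"demand: {exc}") from exc

    try:
        stage("regress")
        counts = counts_by_tract(tracts, facilities)
        regress = stratified_fits(tracts, counts)
        regress.to_csv(out / "regression.csv", index=False)
        manifest["stages"]["regress"] = {"rows": len(regress)}
    except Exception as exc:
        raise PipelineError(f"regress: {exc}") from exc

    try:
        stage("allocate")
        sc = config.scenario
        extent = (0.0, 0.0, sc.width_km, sc.height_km)
        cell = config.cell_km or default_cell_km(extent, len(facilities))
        candidates = fishnet_candidates(extent, cell, network)
        cand_nodes = {c.site_id: c.node_id for c in candidates}
        all_dest = {**fac_dest, **cand_nodes}
        matrix = travel_matrix(network, origins, all_dest)
        county_of = {t.tract_id: t.county for t in tracts}
        from .allocation import Site
        required = [Site(site_id=f.facility_id, capacity=f.capacity)
                    for f in facilities]
        summary_rows = []
        for name in config.specs:
            spec = spec_tables[name]
            points = [DemandPoint(tract_id=t, weight=w, county=county_of[t])
                      for t, w in spec.annual_screenings.items()]
            problem = AllocationProblem(
                demand_points=points, required_sites=required,
                candidates=candidates, p=max(config.p_values),
                matrix=matrix, cutoff_minutes=config.cutoff_minutes)
            results = cumulative_siting(problem, config.p_values)
            (out / f"allocation_{name}.json").write_text(json.dumps(
                _allocation_json(name, results, config.cutoff_minutes),
                sort_keys=True, indent=1))
            for p, res in results.items():
                summary_rows.append({
                    "spec": name, "p": p, "opened": ";".join(res.opened),
                    "covered_demand": res.covered_demand,
                    "marginal_coverage": res.marginal_coverage,
                    "pct_drive_reduction": res.pct_drive_reduction})
        import pandas as pd
        pd.DataFrame(summary_rows).to_csv(out / "allocation_summary.csv",
                                          index=False)

        uspstf = spec_tables.get("uspstf") or demand_specification(tracts, "uspstf")
        points = [DemandPoint(tract_id=t, weight=w, county=county_of[t])
                  for t, w in uspstf.annual_screenings.items()]
        n_non_bicoe = sum(1 for f in facilities if not f.bicoe)
        bp = min(config.bicoe_p, n_non_bicoe)
        bicoe_res = bicoe_conversion(facilities, points, fac_matrix, p=bp,
                                     cutoff_minutes=config.cutoff_minutes)
        (out / "allocation_bicoe.json").write_text(json.dumps(
            _allocation_json("bicoe_conversion", {bp: bicoe_res},
                             config.cutoff_minutes), sort_keys=True, indent=1))
        manifest["stages"]["allocate"] = {
            "candidates": len(candidates), "cell_km": cell,
            "bicoe_p": bp}
    except Exception as exc:
        raise PipelineError(f"allocate: {exc}") from exc

    try:
        stage("report")
        inventory_summary(tracts, facilities).to_csv(
            out / "inventory.csv", index=False)
    except Exception as exc:
        raise PipelineError(f"report: {exc}") from exc

    manifest["files"] = {
        p.name: _digest(p) for p in sorted(out.iterdir())
        if p.suffix in {".csv", ".json", ".geojson"} and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
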