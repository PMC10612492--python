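"""End-to-end runs from a YAML/dict configuration, with provenance.

A run config names the inputs (cost raster, parks, zones), the engine and
selection options, and optional experiment blocks (scenario chain, node
sweep).  The pipeline enforces the sentinel contract: a selected node set
is persisted to CSV and re-loaded on re-runs, so identical configs yield
byte-identical indicator tables; re-selection needs an explicit flag.
Every artifact directory gets a provenance record (config hash, seed, node
hash, package version, solver diagnostics summary).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box, shape

from . import __version__ as _version
from . import fileio
from .cost_surface import CostScheme, DEFAULT_SCHEME, ScenarioEdit, apply_protection_overlay
from .indicators import delta_mper
from .model import SentinelNetwork
from .selection import SelectionConfig, filter_candidates, place_node, select_sentinels
from .sufficiency import detect_sufficiency, node_count_sweep
from .synthetic import LandscapeSpec, ParkSpec, generate_landscape, generate_parks, generate_scenario_footprints

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run configuration (see ``load_config`` for the YAML form)."""

    output_dir: str
    cost_raster: str | None = None
    parks: str | None = None
    nodes: str | None = None  # pre-selected sentinel CSV
    zones: dict[str, list[float]] = field(default_factory=dict)  # name -> [xmin,ymin,xmax,ymax]
    scheme_ranks: list[float] | None = None
    connectivity: int = 8
    averaging: str = "conductance"
    diagonal_scaling: bool = False
    solver_tol: float = 1e-10
    selection: dict = field(default_factory=dict)
    scenarios: list[dict] = field(default_factory=list)
    sweep: dict | None = None
    synthetic: dict | None = None
    seed: int = 0
    reselect: bool = False
    baseline_resolution: float | None = None

    def scheme(self) -> CostScheme:
        if self.scheme_ranks is None:
            return DEFAULT_SCHEME
        n = len(self.scheme_ranks)
        return CostScheme(tuple(self.scheme_ranks), tuple(f"rank-{i}" for i in range(n)))


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute overlay → node selection/load → pairwise fit → indicators.

    Optional blocks: sequential scenario edits (each compared to its
    predecessor, dMPER per step) and the node-count sweep.  Returns a dict
    of output paths and headline numbers; stage failures raise with the
    stage name prefixed.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = cfg.scheme()
    rng_seed = int(cfg.seed)

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return deco

    # ---- cost surface ----
    @stage("cost")
    def cost():
        if cfg.cost_raster:
            return fileio.read_cost_raster(cfg.cost_raster)
        if cfg.synthetic:
            spec = LandscapeSpec(seed=rng_seed, **(cfg.synthetic.get("landscape") or {}))
            return generate_landscape(spec)
        raise ValueError("config needs cost_raster or a synthetic block")

    if cfg.baseline_resolution is not None and cfg.baseline_resolution != cost.cell_size:
        warnings.warn(
            f"cost raster resolution {cost.cell_size} m differs from the stored baseline "
            f"{cfg.baseline_resolution} m; indicator values will not be comparable over time"
        )

    # ---- parks ----
    @stage("parks")
    def parks():
        if cfg.parks:
            return fileio.read_parks_geojson(cfg.parks)
        if cfg.synthetic:
            pspec = ParkSpec(seed=rng_seed + 1, **(cfg.synthetic.get("parks") or {}))
            return generate_parks(pspec, cost)
        raise ValueError("config needs parks or a synthetic block")

    surface = apply_protection_overlay(cost, parks, scheme)
    fileio.write_raster(surface, out / "cost_with_overlay.asc")

    # ---- sentinel nodes: load stored set unless reselection is forced ----
    nodes_csv = Path(cfg.nodes) if cfg.nodes else out / "sentinel_nodes.csv"
    zones_by_park: dict[str, str] = {}

    @stage("selection")
    def nodes():
        nonlocal zones_by_park
        if nodes_csv.exists() and not cfg.reselect:
            logger.info("loading stored sentinel set from %s", nodes_csv)
            return fileio.read_nodes_csv(nodes_csv)
        if not cfg.selection:
            picked = parks.ids
        else:
            zones = {
                name: box(*bounds) if isinstance(bounds, (list, tuple)) else shape(bounds)
                for name, bounds in cfg.zones.items()
            }
            sel_cfg = SelectionConfig(
                zones=zones,
                quotas=cfg.selection.get("quotas", {}),
                min_proximity=cfg.selection.get("min_proximity", 100_000.0),
                designations=(
                    set(cfg.selection["designations"]) if "designations" in cfg.selection else None
                ),
                exclude_islands=cfg.selection.get("exclude_islands", True),
                seed=rng_seed + 2,
            )
            cands = filter_candidates(parks, sel_cfg, surface)
            sset = select_sentinels(cands, sel_cfg, template=surface)
            zones_by_park = sset.zones
            if not sset.converged:
                logger.warning("selection shortfall: %s", sset.shortfall)
            picked = sset.park_ids
        placed = [place_node(parks[i], surface, scheme) for i in picked]
        fileio.write_nodes_csv(placed, nodes_csv, surface, zones=zones_by_park)
        return placed

    # ---- pairwise fit + indicators ----
    @stage("pairwise")
    def baseline():
        model = SentinelNetwork(
            surface,
            nodes,
            scheme=scheme,
            connectivity=cfg.connectivity,
            averaging=cfg.averaging,
            diagonal_scaling=cfg.diagonal_scaling,
            solver_tol=cfg.solver_tol,
            label="baseline",
        )
        return model.fit()

    fileio.write_raster(baseline.current_map, out / "current_density.asc", template=surface)
    fileio.write_resistances(baseline.pairwise, out / "baseline")
    iso = baseline.isolation.reset_index()
    iso.to_csv(out / "node_isolation.csv", index=False, float_format="%.12g")

    indicators = {
        "baseline": baseline.report.to_dict(),
        "scenarios": [],
    }

    # ---- scenario chain (cumulative, each step vs its predecessor) ----
    @stage("scenarios")
    def scenario_rows():
        rows = []
        prev = baseline
        model = baseline.model
        for sdef in cfg.scenarios:
            if "cells" in sdef:
                edit = ScenarioEdit(
                    mode=sdef["mode"],
                    cells=frozenset(tuple(c) for c in sdef["cells"]),
                    name=sdef.get("name", sdef["mode"]),
                )
            else:
                edit = generate_scenario_footprints(
                    kind=sdef["mode"],
                    area_km2=float(sdef["area_km2"]),
                    landscape_context=sdef.get("context", "moderate"),
                    cost=model.cost,
                    seed=rng_seed + 100 + len(rows),
                    scheme=scheme,
                )
            model = model.with_edit(edit, label=edit.name)
            res = model.fit()
            d = delta_mper(res.report, prev.report)
            rows.append(
                {"scenario": edit.name, "mode": edit.mode, "mper": res.mper, "delta_mper": d}
            )
            indicators["scenarios"].append(res.report.to_dict())
            prev = res
        return rows

    scenario_df = pd.DataFrame(scenario_rows)
    if len(scenario_df):
        scenario_df.to_csv(out / "scenario_table.csv", index=False, float_format="%.12g")

    # ---- node-count sweep ----
    sweep_result = {}
    if cfg.sweep:
        @stage("sweep")
        def sweep_table():
            return node_count_sweep(
                baseline.model.grid,
                nodes,
                k_values=cfg.sweep.get("k_values"),
                n_samples=cfg.sweep.get("n_samples", 1000),
                seed=rng_seed + 3,
            )

        sweep_table.to_csv(out / "sweep_table.csv", index=False, float_format="%.12g")
        kstar = detect_sufficiency(sweep_table, cfg.sweep.get("rho_threshold", 0.99))
        sweep_result = {"k_star": kstar, "rows": len(sweep_table)}

    # ---- indicator report + provenance ----
    summary = {
        "mper_ohms": baseline.mper,
        "se_ohms": baseline.mper_se,
        "n_pairs": baseline.n_pairs,
        "excluded_pairs": baseline.excluded_pairs,
        "scenarios": scenario_df.to_dict("records") if len(scenario_df) else [],
        "sweep": sweep_result,
    }
    with open(out / "indicator_report.json", "w") as fh:
        json.dump({**summary, "detail": indicators}, fh, indent=2)

    residuals = [d["residual"] for d in baseline.pairwise.diagnostics]
    provenance = {
        "sentinet_version": _version,
        "seed": rng_seed,
        "config_hash": _hash(cfg.__dict__),
        "node_set_hash": _hash([(n.park_id, n.row, n.col) for n in nodes]),
        "resolution_m": cost.cell_size,
        "max_solver_residual": max(residuals) if residuals else 0.0,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)

    return {"output_dir": str(out), **summary, "provenance": provenance}
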