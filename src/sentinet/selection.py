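"""Stratified random selection of sentinel parks and node-pixel placement.

Sentinel nodes are a fixed subset of parks chosen once and reused for every
future re-evaluation, so the selection must be reproducible (seeded), spread
across the study area (zone quotas), and not cluster (minimum pairwise
centroid proximity, default 100 km).  Rejection sampling can fail to fill a
quota when candidates are dense relative to the proximity constraint; a
shortfall is reported, not silently patched — the analyst tops up manually.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .circuit import NodePixel
from .cost_surface import CostRaster, CostScheme, DEFAULT_SCHEME, Park, ParkLayer, rasterize_footprints

__all__ = ["SelectionConfig", "SentinelSet", "filter_candidates", "select_sentinels", "place_node"]


@dataclass
class SelectionConfig:
    """Stratification zones, quotas, and candidate filters for selection."""

    zones: dict[str, BaseGeometry]
    quotas: dict[str, int]
    min_proximity: float = 100_000.0  # map units (m); 100 km default
    designations: set[str] | None = None
    min_area_km2: float | None = None  # default: one cell of the cost raster
    exclude_islands: bool = True
    seed: int = 0
    attempt_budget: int = 10_000

    def __post_init__(self) -> None:
        if self.min_proximity < 0:
            raise ValueError("min_proximity must be >= 0")
        if any(q < 0 for q in self.quotas.values()):
            raise ValueError("zone quotas must be >= 0")
        missing = set(self.quotas) - set(self.zones)
        if missing:
            raise ValueError(f"quotas name unknown zones: {sorted(missing)}")


@dataclass
class SentinelSet:
    """Outcome of a selection run: chosen parks, per-zone tallies, shortfall."""

    park_ids: list[str]
    zones: dict[str, str]  # park_id -> zone name
    attained: dict[str, int]
    shortfall: dict[str, int]
    seed: int

    @property
    def n(self) -> int:
        return len(self.park_ids)

    @property
    def converged(self) -> bool:
        return all(v == 0 for v in self.shortfall.values())

    def add_manual(self, park_ids: list[str], zone_of: dict[str, str]) -> "SentinelSet":
        """Top up a shortfall with analyst-chosen parks (caller re-verifies spacing)."""
        merged = self.park_ids + [p for p in park_ids if p not in self.park_ids]
        zones = {**self.zones, **{p: zone_of.get(p, "manual") for p in park_ids}}
        attained = dict(self.attained)
        for p in park_ids:
            z = zones[p]
            attained[z] = attained.get(z, 0) + 1
        return SentinelSet(merged, zones, attained, dict(self.shortfall), self.seed)


def _zone_of(park: Park, zones: dict[str, BaseGeometry], template: CostRaster | None) -> str | None:
    cx, cy = park.centroid(template)
    pt = Point(cx, cy)
    for name, geom in zones.items():
        if geom.covers(pt):
            return name
    return None


def filter_candidates(
    parks: ParkLayer, cfg: SelectionConfig, cost: CostRaster
) -> ParkLayer:
    """Apply candidacy filters: designation class, minimum area, island flag.

    Minimum area defaults to one raster cell; the boundary case (area equal
    to exactly one cell) is retained — only strictly smaller parks drop.
    """
    min_area = cfg.min_area_km2 if cfg.min_area_km2 is not None else cost.cell_area_km2
    kept = []
    for p in parks:
        if cfg.designations is not None and p.designation not in cfg.designations:
            continue
        if p.area_km2 is None:
            raise ValueError(f"park {p.park_id!r} has no area attribute")
        if p.area_km2 < min_area:
            continue
        if cfg.exclude_islands and p.is_island:
            continue
        kept.append(p)
    if not kept:
        raise ValueError(
            "no candidate parks survive the filters; relax the designation, "
            "area, or island constraints"
        )
    return ParkLayer(kept)


def select_sentinels(
    candidates: ParkLayer,
    cfg: SelectionConfig,
    template: CostRaster | None = None,
) -> SentinelSet:
    """Stratified random draw under a minimum-proximity constraint.

    Per zone, parks are drawn uniformly at random (without replacement,
    seeded); a draw is accepted iff its centroid lies at least
    ``min_proximity`` from every previously accepted centroid across all
    zones.  Zones are processed in sorted name order.  When a quota cannot
    be met the shortfall is reported in the result rather than raised.
    """
    rng = np.random.default_rng(cfg.seed)
    by_zone: dict[str, list[Park]] = {z: [] for z in cfg.quotas}
    for p in candidates:
        z = _zone_of(p, cfg.zones, template)
        if z is not None and z in by_zone:
            by_zone[z].append(p)

    accepted: list[tuple[str, str, float, float]] = []  # (park_id, zone, cx, cy)
    attained = {z: 0 for z in cfg.quotas}
    for zone in sorted(cfg.quotas):
        quota = cfg.quotas[zone]
        pool = list(by_zone[zone])
        attempts = 0
        while attained[zone] < quota and pool and attempts < cfg.attempt_budget:
            attempts += 1
            k = int(rng.integers(len(pool)))
            park = pool.pop(k)
            cx, cy = park.centroid(template)
            ok = all(
                np.hypot(cx - ax, cy - ay) >= cfg.min_proximity for _, _, ax, ay in accepted
            )
            if ok:
                accepted.append((park.park_id, zone, cx, cy))
                attained[zone] += 1

    shortfall = {z: cfg.quotas[z] - attained[z] for z in cfg.quotas}
    return SentinelSet(
        park_ids=[a[0] for a in accepted],
        zones={a[0]: a[1] for a in accepted},
        attained=attained,
        shortfall=shortfall,
        seed=cfg.seed,
    )


def place_node(
    park: Park,
    cost: CostRaster,
    scheme: CostScheme = DEFAULT_SCHEME,
    cells: set[tuple[int, int]] | None = None,
) -> NodePixel:
    """Place the park's sentinel node on a single pixel.

    The centroid cell is used when it belongs to the park footprint and its
    cost equals the lowest cost class present in the park; otherwise the
    node moves to the nearest in-park cell (Euclidean distance between cell
    centers, ties broken row-major) holding that lowest class.  Parks with
    no 0.1 pixel use their next available lowest cost.
    """
    if cells is None:
        cells = rasterize_footprints([park], cost)[park.park_id]
    valid_cells = [(r, c) for r, c in cells if not cost.nodata_mask[r, c]]
    if not valid_cells:
        raise ValueError(f"park {park.park_id!r} has no valid (non-NoData) cells")
    costs = {rc: float(cost.grid[rc]) for rc in valid_cells}
    lowest = min(costs.values())

    cx, cy = park.centroid(cost)
    centroid_cell = cost.cell_of(cx, cy)
    if centroid_cell in costs and costs[centroid_cell] == lowest:
        r, c = centroid_cell
        return NodePixel(park.park_id, r, c, lowest)

    if centroid_cell is None:
        # off-raster centroid: measure from the park's mean cell center instead
        rr = float(np.mean([r for r, _ in valid_cells]))
        cc = float(np.mean([c for _, c in valid_cells]))
    else:
        rr, cc = float(centroid_cell[0]), float(centroid_cell[1])
    best = min(
        (rc for rc in sorted(valid_cells) if costs[rc] == lowest),
        key=lambda rc: ((rc[0] - rr) ** 2 + (rc[1] - cc) ** 2, rc),
    )
    return NodePixel(park.park_id, best[0], best[1], lowest)
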