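"""Cost-surface construction, protection overlays, and scenario edits.

A cost (resistance) surface is a raster whose cell values rank how strongly
landscape features impede animal movement: natural cover is cheap to cross,
roads, cities and large water bodies are near-barriers.  The default scheme
uses five discrete ranks; the lowest rank is reserved for natural cover that
falls inside protected-area boundaries, encoding the assumption that
regulation of human activity makes movement through parks less costly than
through equivalent natural cover outside them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

__all__ = [
    "CostScheme",
    "CostRaster",
    "Park",
    "ParkLayer",
    "ScenarioEdit",
    "rasterize_footprints",
    "rasterize_line",
    "apply_protection_overlay",
    "apply_scenario_edit",
    "DEFAULT_SCHEME",
]


@dataclass(frozen=True)
class CostScheme:
    """Ordered movement-cost ranks and the feature classes they label.

    Ranks are dimensionless resistance multipliers, strictly positive and
    strictly increasing.  By convention ``ranks[0]`` is protected natural
    cover, ``ranks[1]`` unprotected natural cover, and ``ranks[-1]`` the
    barrier class (cities, multi-lane highways, large lakes).
    """

    ranks: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0, 1000.0)
    labels: tuple[str, ...] = (
        "natural areas within protected-area boundaries",
        "natural areas outside protected-area boundaries",
        "minor roads, pasture, young forestry cuts",
        "croplands, two-lane highways",
        "cities, railroads, multi-lane highways, large lakes and rivers",
    )

    def __post_init__(self) -> None:
        ranks = tuple(float(r) for r in self.ranks)
        object.__setattr__(self, "ranks", ranks)
        if len(ranks) < 2:
            raise ValueError("a cost scheme needs at least two ranks")
        if len(self.labels) != len(ranks):
            raise ValueError("one label per rank required")
        if any(r <= 0 for r in ranks):
            raise ValueError("cost ranks must be strictly positive")
        if any(b <= a for a, b in zip(ranks, ranks[1:])):
            raise ValueError("cost ranks must be strictly increasing")

    @property
    def protected_rank(self) -> float:
        return self.ranks[0]

    @property
    def natural_rank(self) -> float:
        return self.ranks[1]

    @property
    def highest_rank(self) -> float:
        return self.ranks[-1]


DEFAULT_SCHEME = CostScheme()


@dataclass
class CostRaster:
    """A 2-D grid of per-cell movement costs with a NoData mask.

    Row 0 is the northernmost row; ``origin`` is the (x, y) of the
    lower-left corner of the grid in projected map units (the ESRI ASCII
    convention).  ``crs`` is an opaque tag carried through I/O.
    """

    grid: np.ndarray
    nodata_mask: np.ndarray | None = None
    cell_size: float = 300.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 2-D array")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.grid.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.grid.shape:
            raise ValueError("nodata_mask shape must match grid shape")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        valid = self.grid[~self.nodata_mask]
        if valid.size and (not np.all(np.isfinite(valid)) or np.any(valid <= 0)):
            bad = np.argwhere(~self.nodata_mask & ~(np.isfinite(self.grid) & (self.grid > 0)))
            raise ValueError(
                "non-positive or non-finite cost outside NoData at cells "
                f"{[(int(r), int(c)) for r, c in bad[:10]]}" + ("..." if len(bad) > 10 else "")
            )

    @classmethod
    def unchecked(
        cls,
        grid: np.ndarray,
        nodata_mask: np.ndarray,
        cell_size: float = 1.0,
        origin: tuple[float, float] = (0.0, 0.0),
        crs: str | None = None,
    ) -> "CostRaster":
        """Build without the positivity invariant (for current-density grids)."""
        obj = object.__new__(cls)
        obj.grid = np.asarray(grid, dtype=float)
        obj.nodata_mask = np.asarray(nodata_mask, dtype=bool)
        obj.cell_size = float(cell_size)
        obj.origin = tuple(origin)
        obj.crs = crs
        return obj

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def n_valid(self) -> int:
        return int((~self.nodata_mask).sum())

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in map units."""
        nrows, ncols = self.grid.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + ncols * self.cell_size, y0 + nrows * self.cell_size)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        nrows = self.grid.shape[0]
        x0, y0 = self.origin
        return (
            x0 + (col + 0.5) * self.cell_size,
            y0 + (nrows - row - 0.5) * self.cell_size,
        )

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        """Cell containing a map-coordinate point, or None outside the extent."""
        nrows, ncols = self.grid.shape
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(nrows - 1 - np.floor((y - y0) / self.cell_size))
        if 0 <= row < nrows and 0 <= col < ncols:
            return (row, col)
        return None

    def copy(self) -> "CostRaster":
        return CostRaster(
            self.grid.copy(), self.nodata_mask.copy(), self.cell_size, self.origin, self.crs
        )


@dataclass
class Park:
    """A protected area: footprint polygon or explicit cell set, plus attributes."""

    park_id: str
    geometry: BaseGeometry | None = None
    designation: str = "Provincial Park"
    area_km2: float | None = None
    is_island: bool = False
    cells: frozenset[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.geometry is None and self.cells is None:
            raise ValueError(f"park {self.park_id!r} needs a geometry or a cell set")
        if self.area_km2 is None and self.geometry is not None:
            self.area_km2 = float(self.geometry.area) / 1e6

    def centroid(self, template: CostRaster | None = None) -> tuple[float, float]:
        if self.geometry is not None:
            c = self.geometry.centroid
            return (c.x, c.y)
        if template is None:
            raise ValueError("cell-defined park needs a template raster for its centroid")
        xs, ys = zip(*(template.cell_center(r, c) for r, c in self.cells))
        return (float(np.mean(xs)), float(np.mean(ys)))


class ParkLayer:
    """An id-unique collection of parks."""

    def __init__(self, parks: Iterable[Park]):
        parks = list(parks)
        ids = [p.park_id for p in parks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate park ids: {dupes}")
        self._parks = parks
        self._by_id = {p.park_id: p for p in parks}

    def __iter__(self):
        return iter(self._parks)

    def __len__(self) -> int:
        return len(self._parks)

    def __getitem__(self, park_id: str) -> Park:
        return self._by_id[park_id]

    def __contains__(self, park_id: str) -> bool:
        return park_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [p.park_id for p in self._parks]

    def subset(self, ids: Iterable[str]) -> "ParkLayer":
        return ParkLayer([self._by_id[i] for i in ids])


@dataclass
class ScenarioEdit:
    """A simulated land-use change: a development (barrier) or a new park.

    ``mode='development'`` forces every footprint cell (and any cell crossed
    by the optional road line) to the highest cost rank.  ``mode='park'``
    lowers footprint cells currently at the natural rank to the protected
    rank, leaving roads, water and other high-cost cover inside the new park
    untouched.
    """

    mode: str
    footprint: BaseGeometry | None = None
    cells: frozenset[tuple[int, int]] | None = None
    road: BaseGeometry | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("development", "park"):
            raise ValueError(f"mode must be 'development' or 'park', got {self.mode!r}")
        if self.footprint is None and self.cells is None:
            raise ValueError("scenario edit needs a footprint geometry or cell set")


# ---------------------------------------------------------------------------
# rasterization


def _cells_in_geometry(geom: BaseGeometry, template: CostRaster) -> set[tuple[int, int]]:
    """Cells whose centers fall inside ``geom`` (center-in-polygon rule)."""
    nrows, ncols = template.shape
    xmin, ymin, xmax, ymax = geom.bounds
    x0, y0 = template.origin
    cs = template.cell_size
    c_lo = max(0, int(np.floor((xmin - x0) / cs)))
    c_hi = min(ncols - 1, int(np.floor((xmax - x0) / cs)))
    r_lo = max(0, int(nrows - 1 - np.floor((ymax - y0) / cs)))
    r_hi = min(nrows - 1, int(nrows - 1 - np.floor((ymin - y0) / cs)))
    if c_lo > c_hi or r_lo > r_hi:
        return set()
    rows = np.arange(r_lo, r_hi + 1)
    cols = np.arange(c_lo, c_hi + 1)
    cc, rr = np.meshgrid(cols, rows)
    xs = x0 + (cc + 0.5) * cs
    ys = y0 + (nrows - rr - 0.5) * cs
    inside = shapely.contains_xy(geom, xs.ravel(), ys.ravel())
    return {(int(r), int(c)) for r, c in zip(rr.ravel()[inside], cc.ravel()[inside])}


def rasterize_footprints(
    parks: ParkLayer | Iterable[Park], template: CostRaster
) -> dict[str, set[tuple[int, int]]]:
    """Map each park to the template cells whose centers its footprint covers.

    Parks that cover no cell center collapse to the single cell containing
    their centroid; parks entirely outside the raster extent map to an empty
    set with a warning.
    """
    out: dict[str, set[tuple[int, int]]] = {}
    nrows, ncols = template.shape
    for park in parks:
        if park.cells is not None:
            kept = {(r, c) for r, c in park.cells if 0 <= r < nrows and 0 <= c < ncols}
            if len(kept) < len(park.cells):
                warnings.warn(f"park {park.park_id!r}: cells outside raster extent dropped")
            out[park.park_id] = kept
            continue
        cells = _cells_in_geometry(park.geometry, template)
        if not cells:
            cx, cy = park.centroid(template)
            cell = template.cell_of(cx, cy)
            if cell is None:
                warnings.warn(f"park {park.park_id!r} lies outside the raster extent")
                out[park.park_id] = set()
            else:
                out[park.park_id] = {cell}
        else:
            out[park.park_id] = cells
    return out


def rasterize_line(line: BaseGeometry, template: CostRaster) -> set[tuple[int, int]]:
    """All-touched tracing of a line: every cell the line passes through.

    Implemented by dense sampling along the line at a fifth of the cell size,
    which cannot skip a crossed cell; a 1-cell-wide barrier rasterized this
    way does not leak diagonally under 4-neighbor connectivity.
    """
    step = template.cell_size / 5.0
    n = max(2, int(np.ceil(line.length / step)) + 1)
    pts = [line.interpolate(d) for d in np.linspace(0.0, line.length, n)]
    ordered: list[tuple[int, int]] = []
    for p in pts:
        cell = template.cell_of(p.x, p.y)
        if cell is not None and (not ordered or ordered[-1] != cell):
            ordered.append(cell)
    cells = set(ordered)
    # a line through a cell corner steps diagonally; insert a bridge cell so
    # the traced barrier is 4-connected
    for (r0, c0), (r1, c1) in zip(ordered, ordered[1:]):
        if abs(r0 - r1) == 1 and abs(c0 - c1) == 1:
            cells.add((r1, c0))
    return cells


# ---------------------------------------------------------------------------
# overlays and edits


def apply_protection_overlay(
    cost: CostRaster,
    parks: ParkLayer | Iterable[Park],
    scheme: CostScheme = DEFAULT_SCHEME,
    footprints: Mapping[str, set[tuple[int, int]]] | None = None,
) -> CostRaster:
    """Lower natural cover inside park boundaries to the protected rank.

    Only cells exactly at the natural rank change; roads, water and other
    high-cost cover inside parks keep their original costs.  Idempotent.
    """
    if footprints is None:
        footprints = rasterize_footprints(parks, cost)
    out = cost.copy()
    for cells in footprints.values():
        for r, c in cells:
            if not out.nodata_mask[r, c] and out.grid[r, c] == scheme.natural_rank:
                out.grid[r, c] = scheme.protected_rank
    return out


def apply_scenario_edit(
    cost: CostRaster, edit: ScenarioEdit, scheme: CostScheme = DEFAULT_SCHEME
) -> CostRaster:
    """Apply one development or park-addition edit, returning a new raster."""
    if edit.cells is not None:
        cells = set(edit.cells)
        nrows, ncols = cost.shape
        cells = {(r, c) for r, c in cells if 0 <= r < nrows and 0 <= c < ncols}
    else:
        cells = _cells_in_geometry(edit.footprint, cost)
    if not cells:
        raise ValueError(f"scenario edit {edit.name!r}: footprint rasterizes to no cells")
    out = cost.copy()
    valid = [(r, c) for r, c in cells if not out.nodata_mask[r, c]]
    if edit.mode == "development":
        for r, c in valid:
            out.grid[r, c] = scheme.highest_rank
        if edit.road is not None:
            for r, c in rasterize_line(edit.road, cost):
                if not out.nodata_mask[r, c]:
                    out.grid[r, c] = scheme.highest_rank
    else:  # park
        for r, c in valid:
            if out.grid[r, c] == scheme.natural_rank:
                out.grid[r, c] = scheme.protected_rank
    return out
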