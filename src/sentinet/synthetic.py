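"""Synthetic cost landscapes, park networks, and scenario footprints.

Every experiment in the package can run on generated data: a spatially
autocorrelated mosaic of the five cost ranks (smoothed Gaussian noise cut
at quantiles, so class fractions hit their targets), random high-cost
polylines standing in for highways and rivers, disk-shaped parks from
buffered random points, and rectangular development / park-addition
footprints placed by landscape context.

Defaults describe a mostly-natural, patchy mosaic: 65 % natural cover,
20 % low-modification (cost 10), 10 % agriculture (cost 100), 5 % barrier
(cost 1000), autocorrelation length 5 cells, one linear feature per 100
columns.  Parks default to 60 points with 300-m buffers on a 300-m grid,
the configuration used for the node-count sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Point

from .cost_surface import CostRaster, CostScheme, DEFAULT_SCHEME, Park, ParkLayer, ScenarioEdit, rasterize_line

__all__ = [
    "LandscapeSpec",
    "ParkSpec",
    "generate_landscape",
    "generate_parks",
    "generate_scenario_footprints",
]


@dataclass
class LandscapeSpec:
    """Recipe for a synthetic cost mosaic."""

    shape: tuple[int, int] = (100, 100)
    cell_size: float = 300.0
    fractions: dict[float, float] = field(
        default_factory=lambda: {10.0: 0.20, 100.0: 0.10, 1000.0: 0.05}
    )
    autocorr_length: float = 5.0  # cells
    linear_density: float = 1.0  # features per 100 columns
    seed: int = 0
    scheme: CostScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("class fractions must be >= 0")
        if sum(self.fractions.values()) > 1.0 + 1e-12:
            raise ValueError("class fractions must sum to <= 1 (remainder is natural cover)")
        unknown = set(self.fractions) - set(self.scheme.ranks)
        if unknown:
            raise ValueError(f"fractions reference costs outside the scheme: {sorted(unknown)}")


@dataclass
class ParkSpec:
    """Recipe for a buffered-point park network."""

    n_parks: int = 60
    buffer_radius: float = 300.0  # map units
    min_spacing: float = 0.0  # between park center points
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parks < 1:
            raise ValueError("n_parks must be >= 1")


def generate_landscape(spec: LandscapeSpec) -> CostRaster:
    """Threshold a smoothed random field into cost classes at target fractions.

    A Gaussian-filtered white-noise field (sigma = autocorrelation length)
    is cut at its own quantiles so that each non-natural class occupies its
    target fraction, higher costs taking the upper tail in rank order;
    the remainder is natural cover (cost 1).  Random straight polylines are
    then burned in at the barrier cost.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    nrows, ncols = spec.shape
    field_ = rng.standard_normal((nrows, ncols))
    if spec.autocorr_length > 0:
        field_ = ndimage.gaussian_filter(field_, sigma=spec.autocorr_length)

    grid = np.full(spec.shape, spec.scheme.natural_rank)
    # carve classes from the top of the field, highest cost last so it wins ties
    costs_sorted = sorted((c for c in spec.fractions if spec.fractions[c] > 0))
    upper = 1.0
    for cost_value in costs_sorted:
        frac = spec.fractions[cost_value]
        lo = np.quantile(field_, upper - frac)
        hi = np.quantile(field_, upper) if upper < 1.0 else np.inf
        grid[(field_ >= lo) & (field_ < hi)] = cost_value
        upper -= frac

    n_lines = int(round(spec.linear_density * ncols / 100.0))
    raster = CostRaster(grid, cell_size=spec.cell_size, crs="synthetic")
    for _ in range(n_lines):
        # straight feature crossing the full extent between two random edge points
        xmin, ymin, xmax, ymax = raster.extent
        if rng.random() < 0.5:  # roughly vertical
            p0 = (rng.uniform(xmin, xmax), ymin)
            p1 = (rng.uniform(xmin, xmax), ymax)
        else:
            p0 = (xmin, rng.uniform(ymin, ymax))
            p1 = (xmax, rng.uniform(ymin, ymax))
        for r, c in rasterize_line(LineString([p0, p1]), raster):
            grid[r, c] = spec.scheme.highest_rank
    return CostRaster(grid, cell_size=spec.cell_size, crs="synthetic")


def generate_parks(spec: ParkSpec, template: CostRaster) -> ParkLayer:
    """Buffered random points: uniform locations, optional minimum spacing.

    Points are rejection-sampled inside the template extent (budget 1,000
    attempts per park); each is buffered to a disk and becomes one park.
    Raises when the spacing constraint cannot be met.
    """
    rng = np.random.default_rng(spec.seed)
    xmin, ymin, xmax, ymax = template.extent
    pts: list[tuple[float, float]] = []
    budget = 1000 * spec.n_parks
    attempts = 0
    while len(pts) < spec.n_parks and attempts < budget:
        attempts += 1
        x, y = rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)
        if all(math.hypot(x - px, y - py) >= spec.min_spacing for px, py in pts):
            pts.append((x, y))
    if len(pts) < spec.n_parks:
        raise ValueError(
            f"could not place {spec.n_parks} parks with spacing {spec.min_spacing} "
            f"in {attempts} attempts; reduce n_parks or spacing"
        )
    parks = [
        Park(
            park_id=f"park-{i + 1:03d}",
            geometry=Point(x, y).buffer(spec.buffer_radius, quad_segs=16),
            designation="Provincial Park",
        )
        for i, (x, y) in enumerate(pts)
    ]
    return ParkLayer(parks)


def _rect_cells(center: tuple[int, int], n_cells: int, shape: tuple[int, int]) -> set[tuple[int, int]]:
    """A compact near-square block of exactly n_cells around a center cell."""
    h = max(1, int(round(math.sqrt(n_cells))))
    w = int(math.ceil(n_cells / h))
    r0 = center[0] - h // 2
    c0 = center[1] - w // 2
    cells = []
    for r in range(r0, r0 + h):
        for c in range(c0, c0 + w):
            cells.append((r, c))
    cells = [(r, c) for r, c in cells if 0 <= r < shape[0] and 0 <= c < shape[1]]
    return set(cells[:n_cells])


def generate_scenario_footprints(
    kind: str,
    area_km2: float,
    landscape_context: str,
    cost: CostRaster,
    seed: int = 0,
    scheme: CostScheme = DEFAULT_SCHEME,
) -> ScenarioEdit:
    """Place a rectangular scenario footprint matched to a landscape context.

    The footprint covers ``ceil(area_km2 / cell_area)`` cells — at least the
    requested area (157 km² on a 300-m grid → 1,745 cells).  Context is matched against terciles of the
    landscape's own smoothed mean-cost surface: ``low`` below the 33rd
    percentile, ``moderate`` between, ``high`` above the 67th.  Development
    footprints gain a straight road polyline to the nearest existing
    barrier-cost cell, standing in for a highway connection.
    """
    if kind not in ("development", "park"):
        raise ValueError("kind must be 'development' or 'park'")
    if landscape_context not in ("low", "moderate", "high"):
        raise ValueError("landscape_context must be 'low', 'moderate', or 'high'")
    n_cells = int(math.ceil(area_km2 / cost.cell_area_km2 - 1e-9))
    nrows, ncols = cost.shape
    if n_cells > 0.25 * nrows * ncols:
        raise ValueError("requested footprint exceeds a quarter of the landscape")
    if n_cells < 1:
        raise ValueError("requested area is smaller than one cell")

    side = max(1, int(round(math.sqrt(n_cells))))
    work = np.where(cost.nodata_mask, np.nan, cost.grid)
    # neighborhood mean cost at the footprint's scale
    filled = np.where(np.isnan(work), np.nanmean(work), work)
    smooth = ndimage.uniform_filter(filled, size=side, mode="nearest")
    valid = ~cost.nodata_mask
    lo, hi = np.percentile(smooth[valid], [100 / 3, 200 / 3])
    if landscape_context == "low":
        ok = smooth <= lo
    elif landscape_context == "high":
        ok = smooth >= hi
    else:
        ok = (smooth > lo) & (smooth < hi)
    ok &= valid
    # keep the footprint inside the raster
    margin_r, margin_c = side // 2 + 1, side // 2 + 1
    interior = np.zeros_like(ok)
    interior[margin_r : nrows - margin_r, margin_c : ncols - margin_c] = True
    candidates = np.argwhere(ok & interior)
    if len(candidates) == 0:
        raise ValueError(f"no {landscape_context}-cost location can host a {area_km2} km² footprint")

    rng = np.random.default_rng(seed)
    center = tuple(candidates[rng.integers(len(candidates))])
    cells = _rect_cells(center, n_cells, cost.shape)

    road = None
    if kind == "development":
        barrier = np.argwhere((cost.grid == scheme.highest_rank) & valid)
        outside = [rc for rc in map(tuple, barrier) if rc not in cells]
        if outside:
            tgt = min(outside, key=lambda rc: (rc[0] - center[0]) ** 2 + (rc[1] - center[1]) ** 2)
            road = LineString([cost.cell_center(*center), cost.cell_center(*tgt)])

    return ScenarioEdit(
        mode=kind,
        cells=frozenset(cells),
        road=road,
        name=f"{kind}-{area_km2:g}km2-{landscape_context}",
    )
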