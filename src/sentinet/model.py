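"""Model/Results interface over the circuit engine and indicators.

:class:`SentinelNetwork` is constructed from data — a cost raster and a
fixed set of sentinel node pixels (or parks, via :meth:`from_parks`) — and
``fit()`` runs the pairwise circuit analysis.  The returned
:class:`SentinelNetworkResults` carries the estimates (MPER and its SE),
per-node isolation, the resistance matrix and cumulative current map,
solver diagnostics, and a ``summary()`` table; scenario simulation and
plotting hang off these two objects.

    >>> model = SentinelNetwork(cost, nodes)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res2 = model.with_edit(development_edit).fit()
    >>> res2.compare(res)   # dMPER, positive = connectivity loss
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd

from . import __version__ as _version
from .circuit import NodePixel, PairwiseResult, PairwiseSolver, build_grid, pairwise_all
from .cost_surface import (
    CostRaster,
    CostScheme,
    DEFAULT_SCHEME,
    ParkLayer,
    ScenarioEdit,
    apply_protection_overlay,
    apply_scenario_edit,
)
from .indicators import IndicatorReport, compare_current_maps, delta_mper
from .selection import place_node

__all__ = ["SentinelNetwork", "SentinelNetworkResults"]


class SentinelNetwork:
    """Circuit-theory connectivity model for a fixed sentinel-node set.

    Parameters
    ----------
    cost
        The cost (resistance) raster, protection overlay already applied.
    nodes
        Sentinel node pixels; the same set must be reused for any result
        meant to be compared over time.
    connectivity, averaging, diagonal_scaling
        Raster-graph construction options (default 8-neighbor, conductance
        averaging, no diagonal scaling).
    solver_tol, direct_limit
        Linear-solver controls: iterative tolerance and the component size
        above which conjugate gradient replaces direct factorization.
    """

    def __init__(
        self,
        cost: CostRaster,
        nodes: list[NodePixel],
        scheme: CostScheme = DEFAULT_SCHEME,
        connectivity: int = 8,
        averaging: str = "conductance",
        diagonal_scaling: bool = False,
        solver_tol: float = 1e-10,
        direct_limit: int = 150_000,
        label: str = "",
    ):
        if len(nodes) < 2:
            raise ValueError("a sentinel network needs at least two nodes")
        self.cost = cost
        self.nodes = list(nodes)
        self.scheme = scheme
        self.connectivity = connectivity
        self.averaging = averaging
        self.diagonal_scaling = diagonal_scaling
        self.solver_tol = solver_tol
        self.direct_limit = direct_limit
        self.label = label
        self._grid = None
        self._solver = None

    @classmethod
    def from_parks(
        cls,
        cost: CostRaster,
        parks: ParkLayer,
        sentinel_ids: list[str] | None = None,
        scheme: CostScheme = DEFAULT_SCHEME,
        apply_overlay: bool = True,
        **engine_options,
    ) -> "SentinelNetwork":
        """Build the model from park footprints: overlay, then node placement.

        All parks enter the protection overlay (non-node parks still lower
        the cost surface); only ``sentinel_ids`` (default: all) become
        nodes, each placed on its centroid or nearest lowest-cost pixel.
        """
        surface = apply_protection_overlay(cost, parks, scheme) if apply_overlay else cost
        ids = sentinel_ids if sentinel_ids is not None else parks.ids
        nodes = [place_node(parks[i], surface, scheme) for i in ids]
        return cls(surface, nodes, scheme=scheme, **engine_options)

    @property
    def grid(self):
        if self._grid is None:
            self._grid = build_grid(
                self.cost,
                connectivity=self.connectivity,
                averaging=self.averaging,
                diagonal_scaling=self.diagonal_scaling,
            )
            self._solver = PairwiseSolver(
                self._grid, direct_limit=self.direct_limit, tol=self.solver_tol
            )
        return self._grid

    def fit(self) -> "SentinelNetworkResults":
        """Solve all node pairs; return estimates, diagnostics and maps."""
        grid = self.grid
        pw = pairwise_all(grid, self.nodes, solver=self._solver)
        report = IndicatorReport.from_pairwise(pw, label=self.label)
        return SentinelNetworkResults(model=self, pairwise=pw, report=report)

    def with_edit(self, edit: ScenarioEdit, label: str = "") -> "SentinelNetwork":
        """A new model on the edited cost surface, same sentinel set."""
        edited = apply_scenario_edit(self.cost, edit, self.scheme)
        return SentinelNetwork(
            edited,
            self.nodes,
            scheme=self.scheme,
            connectivity=self.connectivity,
            averaging=self.averaging,
            diagonal_scaling=self.diagonal_scaling,
            solver_tol=self.solver_tol,
            direct_limit=self.direct_limit,
            label=label or edit.name,
        )


@dataclass
class SentinelNetworkResults:
    """Fitted connectivity state: indicator estimates, maps, diagnostics."""

    model: SentinelNetwork
    pairwise: PairwiseResult
    report: IndicatorReport

    # -- estimates --------------------------------------------------------

    @property
    def mper(self) -> float:
        """Mean pairwise effective resistance (ohms); lower = better connected."""
        return self.report.mper

    @property
    def mper_se(self) -> float:
        return self.report.se

    @property
    def n_pairs(self) -> int:
        return self.report.n_pairs

    @property
    def excluded_pairs(self) -> int:
        return self.report.excluded_pairs

    @property
    def isolation(self) -> pd.Series:
        return self.report.isolation

    @property
    def resistances(self) -> pd.DataFrame:
        ids = [nd.park_id for nd in self.pairwise.nodes]
        return pd.DataFrame(self.pairwise.resistances, index=ids, columns=ids)

    @property
    def current_map(self) -> np.ndarray:
        return self.pairwise.cumulative_current

    def mean_current(self) -> float:
        return self.pairwise.mean_current()

    # -- comparisons ------------------------------------------------------

    def compare(self, baseline: "SentinelNetworkResults") -> float:
        """dMPER against a baseline fitted on the same sentinel set."""
        return delta_mper(self.report, baseline.report)

    def map_correlation(
        self, other: "SentinelNetworkResults", n_samples: int = 1000, seed: int | None = 0
    ) -> float:
        """Spearman rho between the two cumulative current maps."""
        return compare_current_maps(
            self.current_map, other.current_map, n_samples=n_samples, seed=seed
        )

    # -- presentation -----------------------------------------------------

    def summary(self) -> str:
        """Human-readable summary table of the fitted network."""
        g = self.model.grid
        iso = self.isolation
        finite_iso = iso[np.isfinite(iso)]
        lines = [
            "        Sentinel Network Connectivity Results",
            "=" * 56,
            f"{'Label:':<28}{self.report.label or '(unlabelled)'}",
            f"{'Sentinel nodes:':<28}{self.pairwise.n_nodes}",
            f"{'Node pairs solved:':<28}{self.pairwise.n_pairs}",
            f"{'Unreachable pairs:':<28}{self.excluded_pairs}",
            f"{'Grid cells (valid):':<28}{g.n_nodes}",
            f"{'Graph edges:':<28}{g.n_edges}",
            f"{'Connectivity:':<28}{g.connectivity}-neighbor, {g.averaging} averaging",
            "-" * 56,
            f"{'MPER (ohms):':<28}{self.mper:.6g}",
            f"{'SE (ohms):':<28}{self.mper_se:.6g}",
            f"{'Mean current (A):':<28}{self.mean_current():.6g}",
            f"{'Isolation min/median/max:':<28}"
            f"{finite_iso.min():.6g} / {finite_iso.median():.6g} / {finite_iso.max():.6g}",
            f"{'Most isolated node:':<28}{finite_iso.idxmax()}",
            "=" * 56,
            f"sentinet {_version}; SE = sd(pairwise R)/sqrt(n_pairs)",
        ]
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------

    def plot_current(self, ax=None, log: bool = True, **imshow_kw):
        """Render the cumulative current-density map (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = self.current_map
        if log:
            with np.errstate(divide="ignore"):
                data = np.log10(np.where(data > 0, data, np.nan))
        im = ax.imshow(data, **imshow_kw)
        rows = [nd.row for nd in self.pairwise.nodes]
        cols = [nd.col for nd in self.pairwise.nodes]
        ax.scatter(cols, rows, s=12, c="k", marker="o")
        ax.set_title("Cumulative current density" + (" (log10 A)" if log else " (A)"))
        plt.colorbar(im, ax=ax, shrink=0.8)
        return ax

    def plot_isolation(self, ax=None):
        """Histogram of node-isolation values with the MPER marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        vals = self.isolation[np.isfinite(self.isolation)]
        ax.hist(vals, bins="auto", edgecolor="k")
        ax.axvline(self.mper, color="r", ls="--", label=f"MPER = {self.mper:.4g}")
        ax.set_xlabel("node isolation (ohms)")
        ax.set_ylabel("count")
        ax.legend()
        return ax
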