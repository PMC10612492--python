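"""Raster-to-resistor-network conversion and pairwise circuit solves.

The landscape is modelled as a resistor network: every valid raster cell is
a node, neighboring cells are joined by a resistor whose value combines the
two cell costs, and a unit current injected between a pair of park nodes
spreads over all possible paths.  Two quantities fall out of the solve:

* **effective resistance** between the pair — the voltage needed to push
  1 A between them, lower when more (or cheaper) parallel pathways exist;
* **current density** per cell — the throughflow each cell carries, which
  is proportional to the net probability a random walker travelling from
  source to ground uses that cell.

Summing per-pair current maps over every unordered node pair gives the
cumulative current-density map; averaging the pairwise resistances gives
the MPER connectivity indicator (see :mod:`sentinet.indicators`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import cg, splu

from .cost_surface import CostRaster

__all__ = [
    "ResistorGrid",
    "NodePixel",
    "PairwiseResult",
    "build_grid",
    "solve_pair",
    "pairwise_all",
    "oracle_resistance",
    "PairwiseSolver",
]

logger = logging.getLogger(__name__)

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class NodePixel:
    """A sentinel node: a single raster cell standing for one park."""

    park_id: str
    row: int
    col: int
    cost: float = np.nan

    @property
    def cell(self) -> tuple[int, int]:
        return (self.row, self.col)


@dataclass
class ResistorGrid:
    """Graph view of a cost raster.

    ``node_ids`` maps valid (row, col) cells to consecutive graph node ids
    (-1 for NoData).  Edges join neighboring valid cells; conductance
    combines the two cell costs under the chosen averaging rule:

    * ``averaging='conductance'``: g = (1/c_a + 1/c_b) / 2
    * ``averaging='resistance'``:  g = 1 / ((c_a + c_b) / 2)

    With ``diagonal_scaling`` on, diagonal edges have their resistance
    multiplied by sqrt(2) to account for the longer traverse.
    """

    node_ids: np.ndarray
    cells: np.ndarray  # (n_nodes, 2) int array of (row, col)
    edges_i: np.ndarray
    edges_j: np.ndarray
    conductance: np.ndarray
    components: np.ndarray
    connectivity: int
    averaging: str
    diagonal_scaling: bool
    shape: tuple[int, int] = (0, 0)
    _laplacian: sp.csr_matrix | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.cells)

    @property
    def n_edges(self) -> int:
        return len(self.conductance)

    @property
    def n_components(self) -> int:
        return int(self.components.max()) + 1 if self.n_nodes else 0

    def node_at(self, row: int, col: int) -> int:
        nid = int(self.node_ids[row, col])
        if nid < 0:
            raise ValueError(f"cell ({row}, {col}) is NoData")
        return nid

    def laplacian(self) -> sp.csr_matrix:
        """Weighted graph Laplacian L = D - A (cached)."""
        if self._laplacian is None:
            n = self.n_nodes
            i, j, g = self.edges_i, self.edges_j, self.conductance
            rows = np.concatenate([i, j, i, j])
            cols = np.concatenate([j, i, i, j])
            vals = np.concatenate([-g, -g, g, g])
            self._laplacian = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        return self._laplacian


def build_grid(
    cost: CostRaster,
    connectivity: int = 8,
    averaging: str = "conductance",
    diagonal_scaling: bool = False,
) -> ResistorGrid:
    """Convert a cost raster to a resistor network (one node per valid cell)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if averaging not in ("conductance", "resistance"):
        raise ValueError("averaging must be 'conductance' or 'resistance'")
    valid = ~cost.nodata_mask
    n = int(valid.sum())
    if n == 0:
        raise ValueError("all cells are NoData; nothing to build")
    node_ids = np.full(cost.shape, -1, dtype=np.int64)
    node_ids[valid] = np.arange(n)
    cells = np.argwhere(valid)

    offsets = [(0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(1, 1), (1, -1)]

    ei, ej, gs = [], [], []
    grid = cost.grid
    for dr, dc in offsets:
        a = node_ids[
            max(0, -dr) : node_ids.shape[0] - max(0, dr),
            max(0, -dc) : node_ids.shape[1] - max(0, dc),
        ]
        b = node_ids[
            max(0, dr) : node_ids.shape[0] - max(0, -dr),
            max(0, dc) : node_ids.shape[1] - max(0, -dc),
        ]
        ok = (a >= 0) & (b >= 0)
        ia, ib = a[ok], b[ok]
        ca = grid[cells[ia, 0], cells[ia, 1]]
        cb = grid[cells[ib, 0], cells[ib, 1]]
        if averaging == "conductance":
            g = 0.5 * (1.0 / ca + 1.0 / cb)
        else:
            g = 1.0 / (0.5 * (ca + cb))
        if diagonal_scaling and (dr, dc) in ((1, 1), (1, -1)):
            g = g / _SQRT2  # resistance scaled by sqrt(2)
        ei.append(ia)
        ej.append(ib)
        gs.append(g)

    edges_i = np.concatenate(ei) if ei else np.empty(0, dtype=np.int64)
    edges_j = np.concatenate(ej) if ej else np.empty(0, dtype=np.int64)
    conduct = np.concatenate(gs) if gs else np.empty(0)
    if conduct.size and (not np.all(np.isfinite(conduct)) or np.any(conduct <= 0)):
        raise ValueError("non-positive or non-finite conductance produced; check cost values")

    adj = sp.coo_matrix(
        (np.ones(len(edges_i)), (edges_i, edges_j)), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    return ResistorGrid(
        node_ids=node_ids,
        cells=cells,
        edges_i=edges_i,
        edges_j=edges_j,
        conductance=conduct,
        components=labels,
        connectivity=connectivity,
        averaging=averaging,
        diagonal_scaling=diagonal_scaling,
        shape=cost.shape,
    )


# ---------------------------------------------------------------------------
# solver


class PairwiseSolver:
    """Shared linear-algebra state for many pairwise solves on one grid.

    Per connected component one node is grounded and the reduced Laplacian
    factorized once (sparse LU up to ``direct_limit`` unknowns, otherwise
    Jacobi-preconditioned conjugate gradient at ``tol``).  Each node's
    reduced-inverse column is solved once and cached; any pair's potentials
    are then the difference of two cached columns, exactly equivalent to
    grounding one terminal per solve.
    """

    def __init__(self, grid: ResistorGrid, direct_limit: int = 150_000, tol: float = 1e-10):
        self.grid = grid
        self.direct_limit = direct_limit
        self.tol = tol
        self._factors: dict[int, object] = {}
        self._grounds: dict[int, int] = {}
        self._keep: dict[int, np.ndarray] = {}
        self._columns: dict[int, np.ndarray] = {}
        self._L = grid.laplacian()
        self.last_iterations = 0
        self.last_residual = 0.0

    def _component_system(self, comp: int):
        if comp not in self._factors:
            members = np.flatnonzero(self.grid.components == comp)
            ground = int(members[0])
            keep = members[members != ground]
            sub = self._L[np.ix_(keep, keep)].tocsc()
            if len(keep) == 0:
                self._factors[comp] = None
            elif len(keep) <= self.direct_limit:
                self._factors[comp] = ("lu", splu(sub))
            else:
                self._factors[comp] = ("cg", sub)
            self._grounds[comp] = ground
            self._keep[comp] = keep
        return self._factors[comp], self._grounds[comp], self._keep[comp]

    def potential_column(self, node: int) -> np.ndarray:
        """Full-length potential vector for +1 A at ``node``, component ground at 0 V."""
        if node in self._columns:
            return self._columns[node]
        comp = int(self.grid.components[node])
        factor, ground, keep = self._component_system(comp)
        x = np.zeros(self.grid.n_nodes)
        if node != ground and factor is not None:
            pos = np.searchsorted(keep, node)
            b = np.zeros(len(keep))
            b[pos] = 1.0
            kind, obj = factor
            if kind == "lu":
                sol = obj.solve(b)
                self.last_iterations = 1
            else:
                d = obj.diagonal()
                M = sp.diags(1.0 / d)
                it = [0]

                def _cb(_):
                    it[0] += 1

                sol, info = cg(obj, b, rtol=self.tol, atol=0.0, M=M, callback=_cb, maxiter=20 * len(b))
                self.last_iterations = it[0]
                if info != 0:
                    res = float(np.linalg.norm(obj @ sol - b))
                    raise RuntimeError(
                        f"conjugate gradient failed to converge (info={info}, residual={res:.3e})"
                    )
            x[keep] = sol
        self._columns[node] = x
        return x

    def solve_pair_arrays(self, s: int, t: int):
        """Potentials, effective resistance, and diagnostics for one pair.

        Returns ``(R_eff, v, residual)`` where ``v`` is the node-potential
        vector for +1 A injected at ``s`` and ``t`` grounded at 0 V.
        """
        if s == t:
            raise ValueError("source and ground nodes must differ")
        comps = self.grid.components
        if comps[s] != comps[t]:
            return np.inf, None, 0.0
        xs = self.potential_column(s)
        xt = self.potential_column(t)
        v = xs - xt
        v = v - v[t]  # re-reference so the ground terminal sits at 0 V
        r_eff = float(v[s])
        # residual of L v = e_s - e_t restricted to the component
        b = np.zeros(self.grid.n_nodes)
        b[s], b[t] = 1.0, -1.0
        members = comps == comps[s]
        resid = float(np.max(np.abs((self._L @ v - b)[members]))) if members.any() else 0.0
        self.last_residual = resid
        return r_eff, v, resid

    def node_currents(self, v: np.ndarray, s: int, t: int) -> np.ndarray:
        """Per-node current c_i = (sum of |incident edge currents| + |injection|) / 2.

        Interior nodes report their throughflow; both terminals report the
        full 1 A injected.
        """
        g = self.grid
        flow = np.abs(g.conductance * (v[g.edges_i] - v[g.edges_j]))
        c = np.zeros(g.n_nodes)
        np.add.at(c, g.edges_i, flow)
        np.add.at(c, g.edges_j, flow)
        c[s] += 1.0
        c[t] += 1.0
        return 0.5 * c


@dataclass
class PairwiseResult:
    """Pairwise effective resistances plus the cumulative current-density map.

    ``resistances[i, j]`` is in ohms (``inf`` marks pairs in different
    network components, i.e. unreachable); ``cumulative_current`` is the
    element-wise sum of per-pair current maps in amperes, ``nan`` on NoData.
    """

    nodes: list[NodePixel]
    resistances: np.ndarray
    cumulative_current: np.ndarray
    diagnostics: list[dict] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_pairs(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    @property
    def unreachable_pairs(self) -> int:
        iu = np.triu_indices(self.n_nodes, 1)
        return int(np.isinf(self.resistances[iu]).sum())

    def mean_current(self) -> float:
        return float(np.nanmean(self.cumulative_current))


def solve_pair(
    grid: ResistorGrid,
    s: NodePixel,
    t: NodePixel,
    solver: PairwiseSolver | None = None,
) -> tuple[float, np.ndarray]:
    """Effective resistance and per-cell current map for one node pair.

    Injects +1 A at ``s`` with ``t`` grounded.  Returns ``(R_eff, current)``
    where ``current`` is a raster-shaped array (nan on NoData cells); if the
    nodes sit in different components, ``R_eff`` is ``inf`` and the current
    map is zero on valid cells.
    """
    if s.cell == t.cell:
        raise ValueError(f"source and destination are the same cell {s.cell}")
    if solver is None:
        solver = PairwiseSolver(grid)
    si, ti = grid.node_at(*s.cell), grid.node_at(*t.cell)
    r_eff, v, _ = solver.solve_pair_arrays(si, ti)
    cur = np.full(grid.shape, np.nan)
    rows, cols = grid.cells[:, 0], grid.cells[:, 1]
    if v is None:
        cur[rows, cols] = 0.0
        return np.inf, cur
    c = solver.node_currents(v, si, ti)
    cur[rows, cols] = c
    return r_eff, cur


def pairwise_all(
    grid: ResistorGrid,
    nodes: list[NodePixel],
    solver: PairwiseSolver | None = None,
) -> PairwiseResult:
    """Solve every unordered node pair; sum the per-pair current maps.

    For n nodes this is n(n-1)/2 solves (1,225 pairs for 50 nodes), but the
    factorization and per-node inverse columns are shared, so the marginal
    cost per pair is one vector combination.  Unreachable pairs (different
    components) are recorded as ``inf`` and contribute zero current.
    """
    if len(nodes) < 2:
        raise ValueError("pairwise analysis needs at least two nodes")
    seen: dict[tuple[int, int], str] = {}
    for nd in nodes:
        if nd.cell in seen:
            raise ValueError(
                f"parks {seen[nd.cell]!r} and {nd.park_id!r} share node cell {nd.cell}"
            )
        seen[nd.cell] = nd.park_id
    if solver is None:
        solver = PairwiseSolver(grid)
    n = len(nodes)
    ids = [grid.node_at(*nd.cell) for nd in nodes]
    R = np.zeros((n, n))
    cum = np.zeros(grid.n_nodes)
    diags: list[dict] = []
    unreachable = 0
    for a in range(n):
        for b in range(a + 1, n):
            r_eff, v, resid = solver.solve_pair_arrays(ids[a], ids[b])
            if v is None:
                R[a, b] = R[b, a] = np.inf
                unreachable += 1
                continue
            R[a, b] = R[b, a] = r_eff
            cum += solver.node_currents(v, ids[a], ids[b])
            diags.append(
                {
                    "pair": (nodes[a].park_id, nodes[b].park_id),
                    "iterations": solver.last_iterations,
                    "residual": resid,
                }
            )
    if unreachable:
        logger.warning("%d of %d pairs unreachable (different components)", unreachable, n * (n - 1) // 2)
    cur = np.full(grid.shape, np.nan)
    cur[grid.cells[:, 0], grid.cells[:, 1]] = cum
    return PairwiseResult(nodes=list(nodes), resistances=R, cumulative_current=cur, diagnostics=diags)


def oracle_resistance(grid: ResistorGrid, max_nodes: int = 2000) -> np.ndarray:
    """Dense resistance-distance matrix via the Laplacian pseudoinverse.

    Independent brute-force check for the sparse solver:
    R_ij = L+_ii + L+_jj - 2 L+_ij computed per connected component with a
    dense Moore-Penrose pseudoinverse.  Cross-component pairs are ``inf``.
    Guarded to small grids (``max_nodes``) because it is O(n^3).
    """
    n = grid.n_nodes
    if n > max_nodes:
        raise MemoryError(f"oracle limited to {max_nodes} nodes, grid has {n}")
    L = grid.laplacian().toarray()
    R = np.full((n, n), np.inf)
    np.fill_diagonal(R, 0.0)
    for comp in range(grid.n_components):
        members = np.flatnonzero(grid.components == comp)
        m = len(members)
        # exact pseudoinverse via rank-one deflation of the known nullspace
        # (the all-ones vector): L+ = inv(L + J/m) - J/m.  Avoids the SVD
        # cutoff ambiguity of a generic pinv on near-singular Laplacians.
        J = np.full((m, m), 1.0 / m)
        Lp = np.linalg.inv(L[np.ix_(members, members)] + J) - J
        d = np.diag(Lp)
        Rc = d[:, None] + d[None, :] - 2.0 * Lp
        R[np.ix_(members, members)] = Rc
    return R
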