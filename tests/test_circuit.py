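"""Resistor-grid construction and pairwise solves against independent oracles."""

import networkx as nx
import numpy as np
import pytest

import sentinet as sn
from conftest import random_cost_raster


class TestBuildGrid:
    def test_unit_chain_two_unit_resistors(self, chain3):
        assert chain3.n_nodes == 3
        assert chain3.n_edges == 2
        np.testing.assert_allclose(chain3.conductance, [1.0, 1.0])

    def test_averaging_rules_on_mixed_edge(self):
        raster = sn.CostRaster(np.array([[1.0, 0.1]]))
        g_res = sn.build_grid(raster, connectivity=4, averaging="resistance")
        np.testing.assert_allclose(1.0 / g_res.conductance, [0.55])
        g_con = sn.build_grid(raster, connectivity=4, averaging="conductance")
        np.testing.assert_allclose(g_con.conductance, [5.5])

    def test_nodata_removes_incident_edges(self):
        raster = sn.CostRaster(
            np.ones((2, 2)), nodata_mask=np.array([[False, False], [False, True]])
        )
        g = sn.build_grid(raster, connectivity=4)
        assert g.n_nodes == 3
        assert g.n_edges == 2

    def test_diagonal_scaling_multiplies_resistance_by_sqrt2(self):
        raster = sn.CostRaster(np.ones((2, 2)))
        g = sn.build_grid(raster, connectivity=8, diagonal_scaling=True)
        # 4 orthogonal edges at g=1, 2 diagonal at g=1/sqrt(2)
        diag = np.sort(g.conductance)[:2]
        np.testing.assert_allclose(diag, 1.0 / np.sqrt(2.0))

    def test_all_nodata_is_error(self):
        raster = sn.CostRaster(np.ones((2, 2)), nodata_mask=np.ones((2, 2), dtype=bool))
        with pytest.raises(ValueError):
            sn.build_grid(raster)


class TestSolvePair:
    def test_series_chain(self, chain3):
        R, cur = sn.solve_pair(chain3, sn.NodePixel("a", 0, 0), sn.NodePixel("b", 0, 2))
        assert R == pytest.approx(2.0, abs=1e-10)
        np.testing.assert_allclose(cur, [[1.0, 1.0, 1.0]], atol=1e-10)

    def test_four_cycle_opposite_and_adjacent(self, unit_square):
        R_opp, _ = sn.solve_pair(unit_square, sn.NodePixel("a", 0, 0), sn.NodePixel("b", 1, 1))
        R_adj, _ = sn.solve_pair(unit_square, sn.NodePixel("a", 0, 0), sn.NodePixel("b", 0, 1))
        assert R_opp == pytest.approx(1.0, abs=1e-10)
        assert R_adj == pytest.approx(0.75, abs=1e-10)

    def test_same_cell_is_error(self, chain3):
        with pytest.raises(ValueError):
            sn.solve_pair(chain3, sn.NodePixel("a", 0, 0), sn.NodePixel("b", 0, 0))

    def test_disconnected_pair_unreachable_with_zero_current(self):
        raster = sn.CostRaster(
            np.ones((1, 3)), nodata_mask=np.array([[False, True, False]])
        )
        g = sn.build_grid(raster, connectivity=4)
        R, cur = sn.solve_pair(g, sn.NodePixel("a", 0, 0), sn.NodePixel("b", 0, 2))
        assert np.isinf(R)
        assert cur[0, 0] == 0.0 and cur[0, 2] == 0.0

    def test_matches_networkx_resistance_distance(self, rng):
        """Cross-check against an independent graph-theory implementation."""
        raster = random_cost_raster(rng, (6, 6))
        g = sn.build_grid(raster, connectivity=8)
        G = nx.Graph()
        G.add_nodes_from(range(g.n_nodes))
        for i, j, c in zip(g.edges_i, g.edges_j, g.conductance):
            G.add_edge(int(i), int(j), weight=float(c))
        solver = sn.PairwiseSolver(g)
        for _ in range(5):
            a, b = rng.choice(g.n_nodes, size=2, replace=False)
            # weights are conductances already, so invert_weight must be off
            expected = nx.resistance_distance(G, int(a), int(b), weight="weight", invert_weight=False)
            got, _, _ = solver.solve_pair_arrays(int(a), int(b))
            assert got == pytest.approx(expected, abs=1e-8)

    def test_current_conservation(self, rng):
        """Net signed current is 0 at interior nodes, +/-1 A at the terminals."""
        raster = random_cost_raster(rng, (8, 8))
        g = sn.build_grid(raster, connectivity=8)
        solver = sn.PairwiseSolver(g)
        L = g.laplacian()
        for _ in range(5):
            s, t = rng.choice(g.n_nodes, size=2, replace=False)
            _, v, _ = solver.solve_pair_arrays(int(s), int(t))
            if v is None:
                continue
            net = L @ v  # net injected current at each node
            b = np.zeros(g.n_nodes)
            b[s], b[t] = 1.0, -1.0
            np.testing.assert_allclose(net, b, atol=1e-8)


class TestOracleAndProperties:
    def test_single_edge_oracle(self):
        raster = sn.CostRaster(np.array([[2.0, 2.0]]))
        g = sn.build_grid(raster, connectivity=4, averaging="resistance")
        R = sn.oracle_resistance(g)
        assert R[0, 1] == pytest.approx(2.0)

    def test_oracle_matches_solver_on_random_grids(self, rng):
        for _ in range(5):
            raster = random_cost_raster(rng, (8, 8), nodata_frac=0.1)
            g = sn.build_grid(raster, connectivity=8)
            oracle = sn.oracle_resistance(g)
            solver = sn.PairwiseSolver(g)
            idx = rng.choice(g.n_nodes, size=min(8, g.n_nodes), replace=False)
            for a in idx:
                for b in idx:
                    if a >= b:
                        continue
                    got, _, _ = solver.solve_pair_arrays(int(a), int(b))
                    if np.isinf(oracle[a, b]):
                        assert np.isinf(got)
                    else:
                        assert got == pytest.approx(oracle[a, b], abs=1e-8)

    def test_oracle_memory_guard(self, rng):
        raster = random_cost_raster(rng, (10, 10))
        g = sn.build_grid(raster)
        with pytest.raises(MemoryError):
            sn.oracle_resistance(g, max_nodes=10)

    def test_triangle_inequality(self, rng):
        """Resistance distance is a metric on every connected triple."""
        raster = random_cost_raster(rng, (7, 7))
        g = sn.build_grid(raster, connectivity=8)
        R = sn.oracle_resistance(g)
        idx = rng.choice(g.n_nodes, size=8, replace=False)
        for a in idx:
            for b in idx:
                for c in idx:
                    if len({a, b, c}) == 3 and np.all(np.isfinite(R[[a, a, b], [b, c, c]])):
                        assert R[a, b] <= R[a, c] + R[c, b] + 1e-9

    def test_rayleigh_monotonicity(self, rng):
        """Lowering any cell cost never increases any pairwise resistance."""
        raster = random_cost_raster(rng, (7, 7))
        g0 = sn.build_grid(raster, connectivity=8)
        R0 = sn.oracle_resistance(g0)
        for _ in range(5):
            r2 = raster.copy()
            cell = tuple(rng.integers(0, 7, size=2))
            r2.grid[cell] = 0.1  # decrease (or keep) the cost
            R1 = sn.oracle_resistance(sn.build_grid(r2, connectivity=8))
            assert np.all(R1 <= R0 + 1e-9)

    def test_shortest_path_upper_bound(self, rng):
        """Effective resistance cannot exceed the best single path's resistance."""
        import scipy.sparse as sp
        from scipy.sparse.csgraph import dijkstra

        raster = random_cost_raster(rng, (6, 6))
        g = sn.build_grid(raster, connectivity=8)
        R = sn.oracle_resistance(g)
        W = sp.coo_matrix(
            (1.0 / g.conductance, (g.edges_i, g.edges_j)), shape=(g.n_nodes,) * 2
        )
        D = dijkstra(W, directed=False)
        assert np.all(R <= D + 1e-9)


class TestPairwiseAll:
    def test_pair_count_and_symmetry(self, rng):
        raster = random_cost_raster(rng, (8, 8))
        g = sn.build_grid(raster)
        cells = [tuple(map(int, c)) for c in g.cells[rng.choice(g.n_nodes, 6, replace=False)]]
        nodes = [sn.NodePixel(f"p{i}", r, c) for i, (r, c) in enumerate(cells)]
        res = sn.pairwise_all(g, nodes)
        assert res.n_pairs == 15
        np.testing.assert_array_equal(res.resistances, res.resistances.T)
        assert np.all(np.diag(res.resistances) == 0)

    def test_two_nodes_cumulative_equals_single_pair_map(self, chain3):
        nodes = [sn.NodePixel("a", 0, 0), sn.NodePixel("b", 0, 2)]
        res = sn.pairwise_all(chain3, nodes)
        _, single = sn.solve_pair(chain3, *nodes)
        np.testing.assert_allclose(res.cumulative_current, single, atol=1e-12)

    def test_three_collinear_nodes_series_law(self, chain3):
        nodes = [sn.NodePixel("a", 0, 0), sn.NodePixel("b", 0, 1), sn.NodePixel("c", 0, 2)]
        res = sn.pairwise_all(chain3, nodes)
        np.testing.assert_allclose(
            res.resistances, [[0, 1, 2], [1, 0, 1], [2, 1, 0]], atol=1e-10
        )

    def test_duplicate_node_cells_error_names_parks(self, chain3):
        nodes = [sn.NodePixel("first", 0, 0), sn.NodePixel("second", 0, 0)]
        with pytest.raises(ValueError, match="first.*second"):
            sn.pairwise_all(chain3, nodes)


def test_cg_path_matches_direct(rng):
    """The iterative solver agrees with direct factorization."""
    raster = random_cost_raster(rng, (12, 12))
    g = sn.build_grid(raster, connectivity=8)
    direct = sn.PairwiseSolver(g)
    iterative = sn.PairwiseSolver(g, direct_limit=0)  # force CG
    for _ in range(3):
        a, b = rng.choice(g.n_nodes, size=2, replace=False)
        rd, _, _ = direct.solve_pair_arrays(int(a), int(b))
        ri, _, _ = iterative.solve_pair_arrays(int(a), int(b))
        assert ri == pytest.approx(rd, abs=1e-7)
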