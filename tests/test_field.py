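"""Admittance-method field solver: assembly, solve, interpolation."""

import math

import numpy as np
import pytest

from retistim.field import (
    analytic_point_source,
    assemble_network,
    branch_conductance,
    potential_at,
    solve_unit_field,
)
from retistim.grid import VoxelGrid


def uniform_grid(n_vox=6, rho=1.0, h=1e-3):
    return VoxelGrid(
        labels=np.ones((n_vox,) * 3, dtype=np.int16),
        spacing=h,
        origin=np.zeros(3),
        tissue_names={1: "medium"},
        resistivity_table={1: rho},
    )


class TestAssembly:
    def test_vitreous_branch_conductance(self):
        # two adjacent vitreous voxels at 0.2 mm spacing
        assert branch_conductance(0.666, 0.666, 2e-4) == pytest.approx(
            3.003e-4, rel=1e-3
        )

    def test_homogeneous_grid_equal_conductances(self):
        sys_ = assemble_network(uniform_grid(rho=2.0, h=1e-3))
        off = -sys_.laplacian.copy()
        off.setdiag(0)
        vals = off.data[off.data != 0]
        assert np.allclose(vals, 2 * 1e-3 / (2 * 2.0))

    def test_doubling_resistivity_halves_conductance(self):
        a = assemble_network(uniform_grid(rho=1.0)).laplacian
        b = assemble_network(uniform_grid(rho=2.0)).laplacian
        assert np.allclose(a.toarray(), 2 * b.toarray())

    def test_laplacian_rows_sum_to_zero(self):
        lap = assemble_network(uniform_grid()).laplacian
        assert np.allclose(np.asarray(lap.sum(axis=1)).ravel(), 0.0)


class TestSolve:
    def test_kirchhoff_at_every_node(self):
        grid = uniform_grid(8)
        sys_ = assemble_network(grid)
        nd = grid.node_dims
        src = np.array([np.ravel_multi_index((1, 1, 1), nd)])
        snk = np.array([np.ravel_multi_index((7, 7, 7), nd)])
        sol = solve_unit_field(sys_, src, snk)
        resid = sys_.laplacian @ sol.potentials
        resid[src] -= 1.0
        resid[snk] += 1.0
        assert np.abs(resid).max() <= 1e-8  # relative to 1 A injected

    def test_swapping_sources_and_sinks_negates_differences(self):
        grid = uniform_grid(7)
        sys_ = assemble_network(grid)
        nd = grid.node_dims
        a = np.array([np.ravel_multi_index((1, 2, 3), nd)])
        b = np.array([np.ravel_multi_index((5, 5, 5), nd)])
        v1 = solve_unit_field(sys_, a, b).potentials
        v2 = solve_unit_field(sys_, b, a).potentials
        d1 = v1 - v1.mean()
        d2 = v2 - v2.mean()
        assert np.allclose(d1, -d2, atol=1e-10)

    def test_reference_node_at_zero(self):
        grid = uniform_grid(6)
        sys_ = assemble_network(grid)
        nd = grid.node_dims
        sol = solve_unit_field(
            sys_,
            np.array([np.ravel_multi_index((1, 1, 1), nd)]),
            np.array([np.ravel_multi_index((5, 5, 5), nd)]),
        )
        assert sol.potentials[sol.reference_node] == 0.0

    def test_overlapping_electrodes_rejected(self):
        sys_ = assemble_network(uniform_grid())
        with pytest.raises(ValueError):
            solve_unit_field(sys_, np.array([3]), np.array([3, 4]))

    def test_reciprocity_against_dense_oracle(self):
        """Potential at b from a unit source at a equals potential at a
        from a unit source at b (same sink set) -- checked on a grid small
        enough for the dense direct path."""
        grid = uniform_grid(9)  # 10^3 = 1000 nodes, dense solve
        sys_ = assemble_network(grid)
        nd = grid.node_dims
        sink = np.array([np.ravel_multi_index((0, 0, 0), nd)])
        a = np.ravel_multi_index((2, 3, 4), nd)
        b = np.ravel_multi_index((7, 6, 5), nd)
        v_from_a = solve_unit_field(sys_, np.array([a]), sink).potentials
        v_from_b = solve_unit_field(sys_, np.array([b]), sink).potentials
        assert v_from_a[b] == pytest.approx(v_from_b[a], rel=1e-9)

    def test_point_source_matches_analytic_solution(self, homogeneous_field):
        """Homogeneous medium with a central source and a spherical sink
        shell: V(r) = rho*I/(4 pi) (1/r - 1/R_shell) within 5% for
        3h <= r <= domain/4."""
        hf = homogeneous_field
        sol, grid = hf["solution"], hf["grid"]
        h = grid.spacing
        domain = grid.dims[0] * h
        r = hf["node_r"]
        mask = (r >= 3 * h) & (r <= domain / 4)
        v_num = sol.potentials - sol.potentials[hf["sinks"]].mean()
        v_ref = analytic_point_source(hf["rho"], 1.0, r[mask]) - analytic_point_source(
            hf["rho"], 1.0, hf["r_shell"]
        )
        rel = np.abs(v_num[mask] - v_ref) / np.abs(v_ref)
        assert rel.max() < 0.05

    def test_refinement_convergence(self):
        """Halving the spacing changes the potential at fixed physical
        probe points by a decreasing amount."""
        rho, L = 1.0, 8e-3
        probes = np.array([[5e-3, 4e-3, 4e-3], [4e-3, 5.5e-3, 4e-3]])
        vals = []
        for n in (8, 16, 32):
            h = L / n
            grid = uniform_grid(n, rho, h)
            sys_ = assemble_network(grid)
            nd = grid.node_dims
            src = np.array([np.ravel_multi_index((n // 2,) * 3, nd)])
            corners = [0, nd[0] - 1]
            snk = np.array(
                [np.ravel_multi_index((i, j, k), nd)
                 for i in corners for j in corners for k in corners]
            )
            sol = solve_unit_field(sys_, src, snk)
            v = potential_at(sol, probes)
            # probe-point difference: independent of the diverging
            # potential at the point-sink reference
            vals.append(v[0] - v[1])
        d1 = abs(vals[1] - vals[0])
        d2 = abs(vals[2] - vals[1])
        assert d2 < d1


class TestInterpolation:
    def make_solution(self, potentials, grid):
        from retistim.field import FieldSolution

        ref = int(np.argmin(np.abs(potentials)))
        return FieldSolution(
            potentials=potentials - potentials[ref],
            node_dims=grid.node_dims,
            spacing=grid.spacing,
            origin=grid.origin,
            source_nodes=np.array([0]),
            sink_nodes=np.array([ref]),
            reference_node=ref,
            residual=0.0,
        )

    def test_node_identity(self):
        grid = uniform_grid(4)
        v = np.random.default_rng(0).normal(size=grid.n_nodes)
        sol = self.make_solution(v, grid)
        idx = (2, 3, 1)
        pt = grid.node_world(np.array(idx))
        assert potential_at(sol, pt) == pytest.approx(
            sol.potentials.reshape(grid.node_dims)[idx], abs=1e-12
        )

    def test_cell_center_is_mean_of_corners(self):
        grid = uniform_grid(3)
        v = np.random.default_rng(1).normal(size=grid.n_nodes)
        sol = self.make_solution(v, grid)
        corner_mean = sol.potentials.reshape(grid.node_dims)[0:2, 0:2, 0:2].mean()
        center = grid.node_world(np.array([0.5, 0.5, 0.5]))
        assert potential_at(sol, center) == pytest.approx(corner_mean, abs=1e-12)

    def test_exact_on_linear_fields(self):
        grid = uniform_grid(5)
        nd = grid.node_dims
        idx = np.indices(nd).reshape(3, -1).T * grid.spacing
        a = np.array([3.0, -2.0, 0.7]) * 1e3
        v = idx @ a + 0.4
        sol = self.make_solution(v, grid)
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 5 * grid.spacing, size=(20, 3))
        expect = pts @ a + 0.4 - v[sol.reference_node]
        assert np.allclose(potential_at(sol, pts), expect, atol=1e-9)

    def test_out_of_bounds_point_named(self):
        grid = uniform_grid(3)
        sol = self.make_solution(np.zeros(grid.n_nodes), grid)
        with pytest.raises(ValueError, match="0.099"):
            potential_at(sol, np.array([[0.099, 0.0, 0.0]]))


class TestAnalyticPointSource:
    def test_reference_value(self):
        # 100 uA in 0.666 ohm*m at 1 mm
        assert analytic_point_source(0.666, 1e-4, 1e-3) == pytest.approx(
            5.30e-3, rel=1e-3
        )

    def test_inverse_distance_law(self):
        assert analytic_point_source(1.0, 1.0, 2.0) == pytest.approx(
            analytic_point_source(1.0, 1.0, 1.0) / 2
        )

    def test_zero_current_zero_potential(self):
        assert analytic_point_source(1.0, 0.0, 1.0) == 0.0

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            analytic_point_source(1.0, 1.0, 0.0)
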