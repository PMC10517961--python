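"""Admittance-method field solver.

The voxel grid is turned into a 6-connected resistor network on the node
lattice: adjacent nodes i, j at spacing h through material of resistivities
rho_i, rho_j are joined by two half-voxel resistors in series (face area
h^2, length h each side), giving the branch conductance

    G_ij = 2 h / (rho_i + rho_j)    [S]

Exterior faces are open circuits (insulating boundary).  Tissue is treated
as purely resistive (quasi-static), so one unit-current solve per electrode
configuration suffices: the potential for any stimulus current I(t) is
I(t) times the unit solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

from .grid import VoxelGrid

__all__ = [
    "AdmittanceSystem",
    "FieldSolution",
    "assemble_network",
    "solve_unit_field",
    "potential_at",
    "analytic_point_source",
]

DENSE_SOLVE_LIMIT = 10_000  # direct dense solve below this node count


@dataclass
class AdmittanceSystem:
    """Sparse nodal conductance matrix (graph Laplacian) of the lattice."""

    laplacian: sp.csr_matrix  # (n, n), SPD up to the constant null space
    node_dims: tuple[int, int, int]
    spacing: float
    origin: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.laplacian.shape[0]


@dataclass
class FieldSolution:
    """Node potentials per ampere of injected current (unit-current solve)."""

    potentials: np.ndarray  # (n,) V/A
    node_dims: tuple[int, int, int]
    spacing: float
    origin: np.ndarray
    source_nodes: np.ndarray
    sink_nodes: np.ndarray
    reference_node: int
    residual: float

    def __post_init__(self):
        assert abs(self.potentials[self.reference_node]) < 1e-30


def assemble_network(grid: VoxelGrid) -> AdmittanceSystem:
    """Build the resistor-network Laplacian from the voxel grid."""
    rho = grid.node_resistivity()
    if np.any(~np.isfinite(rho)) or np.any(rho <= 0):
        raise ValueError("node resistivities must be finite and positive")
    h = grid.spacing
    nd = grid.node_dims
    n = rho.size
    lin = np.arange(n).reshape(nd)

    rows, cols, vals = [], [], []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        ra, rb = rho[tuple(sl_a)], rho[tuple(sl_b)]
        g = 2.0 * h / (ra + rb)
        rows.append(lin[tuple(sl_a)].ravel())
        cols.append(lin[tuple(sl_b)].ravel())
        vals.append(g.ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)

    i = np.concatenate([rows, cols])
    j = np.concatenate([cols, rows])
    v = np.concatenate([-vals, -vals])
    off = sp.coo_matrix((v, (i, j)), shape=(n, n)).tocsr()
    diag = -np.asarray(off.sum(axis=1)).ravel()
    lap = (off + sp.diags(diag)).tocsr()
    return AdmittanceSystem(lap, nd, h, np.asarray(grid.origin, dtype=float))


def branch_conductance(rho_i: float, rho_j: float, h: float) -> float:
    """Conductance of one lattice branch, G = 2h / (rho_i + rho_j)."""
    return 2.0 * h / (rho_i + rho_j)


def _reference_node(system: AdmittanceSystem, sinks: np.ndarray) -> int:
    """Sink node nearest the sink-set centroid (the solve's ground)."""
    tri = np.array(np.unravel_index(sinks, system.node_dims)).T
    centroid = tri.mean(axis=0)
    k = int(np.argmin(np.linalg.norm(tri - centroid, axis=1)))
    return int(sinks[k])


def solve_unit_field(
    system: AdmittanceSystem,
    sources: np.ndarray,
    sinks: np.ndarray,
    tol: float = 1e-8,
    maxiter: int = 40_000,
) -> FieldSolution:
    """Solve G V = I with +1 A spread uniformly over ``sources`` and -1 A
    over ``sinks``; insulating exterior; potential referenced to the sink
    centroid node.

    The relative residual ||G V - I|| / ||I|| is driven below ``tol`` (CG
    with Jacobi preconditioning; dense direct solve for small systems).
    """
    sources = np.asarray(sources)
    sinks = np.asarray(sinks)
    if sources.size == 0 or sinks.size == 0:
        raise ValueError("source and sink sets must be non-empty")
    if np.intersect1d(sources, sinks).size:
        raise ValueError("source and sink sets must be disjoint")

    L = system.laplacian
    n = L.shape[0]
    b = np.zeros(n)
    b[sources] += 1.0 / sources.size
    b[sinks] -= 1.0 / sinks.size
    ref = _reference_node(system, sinks)

    if n <= DENSE_SOLVE_LIMIT:
        A = L.toarray()
        # ground the reference node to remove the null space
        A[ref, :] = 0.0
        A[:, ref] = 0.0
        A[ref, ref] = 1.0
        rhs = b.copy()
        rhs[ref] = 0.0
        v = np.linalg.solve(A, rhs)
    else:
        d = L.diagonal()
        M = sp.diags(1.0 / d)
        v, info = spla.cg(L, b, rtol=tol * 1e-2, atol=0.0, maxiter=maxiter, M=M)
        if info > 0:
            res = np.linalg.norm(L @ v - b) / np.linalg.norm(b)
            raise RuntimeError(
                f"admittance solve did not converge in {maxiter} iterations "
                f"(relative residual {res:.3e})"
            )

    v = v - v[ref]
    res = float(np.linalg.norm(L @ v - b) / np.linalg.norm(b))
    if res > tol:
        raise RuntimeError(f"admittance solve residual {res:.3e} exceeds {tol:.1e}")
    return FieldSolution(
        potentials=v,
        node_dims=system.node_dims,
        spacing=system.spacing,
        origin=system.origin,
        source_nodes=sources,
        sink_nodes=sinks,
        reference_node=ref,
        residual=res,
    )


def potential_at(solution: FieldSolution, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of node potentials at world points (m).

    Returns V/A values; raises on any out-of-bounds point, naming it.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    axes = [
        solution.origin[k] + np.arange(solution.node_dims[k]) * solution.spacing
        for k in range(3)
    ]
    for k in range(3):
        bad = (pts[:, k] < axes[k][0] - 1e-12) | (pts[:, k] > axes[k][-1] + 1e-12)
        if np.any(bad):
            p = pts[np.nonzero(bad)[0][0]]
            raise ValueError(f"point {tuple(p)} outside the grid bounds")
    interp = RegularGridInterpolator(
        axes, solution.potentials.reshape(solution.node_dims), method="linear"
    )
    out = interp(np.clip(pts, [a[0] for a in axes], [a[-1] for a in axes]))
    return out if np.asarray(points).ndim > 1 else out[0]


def analytic_point_source(rho: float, current: float, r: float | np.ndarray) -> float | np.ndarray:
    """Potential of a point current source in an infinite homogeneous medium,
    V = rho * I / (4 pi r).  The standard solver oracle."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    out = rho * current / (4.0 * math.pi * r)
    return float(out) if out.ndim == 0 else out
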