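"""Shared fixtures.

The expensive artifacts -- the default head-eye grid, the two unit-current
field solves and the strength-duration threshold tables -- are built once
per session and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from retistim.cells import build_bc_cell, build_rgc_cell
from retistim.engine import CellModel, SimulationConfig
from retistim.field import assemble_network, potential_at, solve_unit_field
from retistim.grid import build_head_eye_model, tes1_preset, tes2_preset
from retistim.kinetics import bc_kinetics, rgc_kinetics
from retistim.thresholds import (
    DEFAULT_DURATIONS_MS,
    ThresholdSearch,
    strength_duration,
)

settings.register_profile(
    "repro",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_grid():
    return build_head_eye_model()


@pytest.fixture(scope="session")
def electrode_pairs(default_grid):
    return {"TES1": tes1_preset(default_grid), "TES2": tes2_preset(default_grid)}


@pytest.fixture(scope="session")
def fields(default_grid, electrode_pairs):
    system = assemble_network(default_grid)
    return {
        name: solve_unit_field(system, pair.stimulating, pair.returning)
        for name, pair in electrode_pairs.items()
    }


@pytest.fixture(scope="session")
def bc_model(default_grid):
    return CellModel(build_bc_cell(default_grid), bc_kinetics())


@pytest.fixture(scope="session")
def rgc_model(default_grid):
    return CellModel(build_rgc_cell(default_grid), rgc_kinetics())


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def unit_fields(fields, bc_model, rgc_model):
    """Per-compartment unit-field potentials (V/A) for each cell/config."""
    out = {}
    for cell_name, model in (("bc", bc_model), ("rgc", rgc_model)):
        pts = model.cell.chain.midpoint_m
        for cfg_name, sol in fields.items():
            out[cell_name, cfg_name] = potential_at(sol, pts)
    return out


@pytest.fixture(scope="session")
def threshold_tables(bc_model, rgc_model, unit_fields, sim_config):
    """Strength-duration curves: biphasic under TES1/TES2 for both cells,
    monophasic under TES2.  The BC under TES1 genuinely needs more than
    the default 1e6 uA cap (that inefficiency is the selectivity finding),
    so the search cap is raised for these curves."""
    search = ThresholdSearch(cap_ua=1e8)
    models = {"bc": bc_model, "rgc": rgc_model}
    tables = {}
    for cell_name, model in models.items():
        for cfg_name in ("TES1", "TES2"):
            tables[cell_name, cfg_name, "biphasic"] = strength_duration(
                model, unit_fields[cell_name, cfg_name], DEFAULT_DURATIONS_MS,
                "biphasic", cfg_name, config=sim_config, search=search,
            )
        tables[cell_name, "TES2", "monophasic"] = strength_duration(
            model, unit_fields[cell_name, "TES2"], DEFAULT_DURATIONS_MS,
            "monophasic", "TES2", config=sim_config, search=search,
        )
    return tables


@pytest.fixture(scope="session")
def homogeneous_field():
    """Point source at the center of a homogeneous block with a spherical
    sink shell: the finite-domain analogue of the analytic point source."""
    from retistim.grid import HeadEyeConfig, VoxelGrid

    rho = 0.666
    n_vox = 40
    h = 0.25e-3
    labels = np.ones((n_vox, n_vox, n_vox), dtype=np.int16)
    grid = VoxelGrid(
        labels=labels,
        spacing=h,
        origin=np.zeros(3),
        tissue_names={1: "vitreous"},
        resistivity_table={1: rho},
    )
    system = assemble_network(grid)
    nd = grid.node_dims
    center = np.array([n_vox // 2] * 3)
    idx = np.indices(nd).reshape(3, -1).T
    r = np.linalg.norm((idx - center) * h, axis=1)
    r_shell = 0.45 * n_vox * h
    sinks = np.nonzero(np.abs(r - r_shell) <= h / 2)[0]
    source = np.ravel_multi_index(tuple(center), nd)
    sol = solve_unit_field(system, np.array([source]), sinks)
    return {"grid": grid, "solution": sol, "rho": rho, "r_shell": r_shell,
            "center_m": center * h, "node_r": r, "sinks": sinks,
            "source": source}
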