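"""Experiment configuration: schema validation and end-to-end runs.

A single YAML config drives the full pipeline -- voxel grid, electrode
presets, field solves, cell building, threshold curves and the Shannon
safety chart -- with deterministic, fixed-precision outputs (CSV + HDF5 +
JSON manifest).  Two bundled configs reproduce the package's headline
analyses: ``ratio`` (TES1/TES2 threshold-ratio curves for both cells) and
``safety`` (the corneal-ring Shannon chart).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cells import build_bc_cell, build_rgc_cell
from .engine import CellModel, SimulationConfig
from .field import FieldSolution, assemble_network, potential_at, solve_unit_field
from .grid import HeadEyeConfig, VoxelGrid, build_head_eye_model, tes1_preset, tes2_preset
from .kinetics import bc_kinetics, load_kinetics, rgc_kinetics
from .shannon import max_safe_amplitude, ring_electrode_area, shannon_chart
from .thresholds import (
    DEFAULT_DURATIONS_MS,
    ThresholdSearch,
    strength_duration,
    threshold_ratio,
)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.9g"  # fixed output precision for reproducibility


@dataclass
class ExperimentConfig:
    """Validated experiment description (see bundled YAML for the schema)."""

    grid: HeadEyeConfig = field(default_factory=HeadEyeConfig)
    electrode_configs: tuple[str, ...] = ("TES1", "TES2")
    ring_diameter_mm: float = 3.0
    needle_exposed_mm: float = 2.0
    cells: tuple[str, ...] = ("bc", "rgc")
    kinetics_paths: dict = field(default_factory=dict)  # cell -> yaml path or None
    waveform_kinds: tuple[str, ...] = ("biphasic",)
    durations_ms: tuple[float, ...] = DEFAULT_DURATIONS_MS
    search: ThresholdSearch = field(default_factory=lambda: ThresholdSearch(cap_ua=1e8))
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    safety_amplitudes_ua: tuple[float, ...] = (20.0, 50.0, 100.0, 200.0, 300.0, 400.0)
    safety_phase_ms: float = 10.0
    safety_ring_inner_mm: float = 3.0
    safety_wire_mm: float = 0.27
    safety_contact_fraction: float = 1.0
    safety_k_limit: float = 1.5
    output_dir: Path = Path("retistim_out")
    seed: int = 0
    stages: tuple[str, ...] = ("field", "thresholds", "safety")
    raw: dict = field(default_factory=dict)


def _diag(cond: bool, msg: str, out: list[str]) -> None:
    if cond:
        out.append(msg)


def validate_config(source) -> list[str]:
    """Schema-check a config; returns a list of diagnostics (empty = valid)."""
    if isinstance(source, (str, Path)):
        try:
            doc = yaml.safe_load(Path(source).read_text())
        except OSError as e:
            raise OSError(f"cannot read config {source}: {e}") from e
    else:
        doc = source
    diags: list[str] = []
    if not isinstance(doc, dict):
        return ["config is not a mapping"]
    known = {"grid", "tissues", "electrodes", "cells", "kinetics", "waveforms",
             "search", "simulation", "safety", "output", "seed", "stages"}
    for k in doc:
        _diag(k not in known, f"unknown config block {k!r}", diags)

    g = doc.get("grid", {}) or {}
    grid_fields = {f.name.replace("_mm", "") for f in dataclasses.fields(HeadEyeConfig)}
    for k in g:
        _diag(k.replace("_mm", "") not in grid_fields,
              f"grid: unknown key {k!r}", diags)
    _diag(g.get("spacing_mm", 0.2) <= 0, "grid: spacing_mm must be positive", diags)
    _diag(
        g.get("spacing_mm", 0.2) > g.get("retina_thickness_mm", 0.2),
        "grid: spacing exceeds retina thickness (retina shell would vanish)",
        diags,
    )
    tissues = doc.get("tissues", {}) or {}
    for name, rho in tissues.items():
        _diag(not isinstance(rho, (int, float)) or rho <= 0,
              f"tissues: {name} resistivity must be a positive number", diags)
    required = {"muscle", "skin", "fat", "brain", "vitreous", "retina", "lens",
                "cornea"}
    if tissues:
        merged = set(tissues)
        _diag(not required <= merged,
              f"tissues: missing resistivity for {sorted(required - merged)}", diags)

    sim = doc.get("simulation", {}) or {}
    _diag(sim.get("dt_ms", 0.01) <= 0, "simulation: dt_ms must be positive", diags)
    _diag(sim.get("settle_ms", 400.0) < 0, "simulation: settle_ms must be >= 0", diags)
    thr = sim.get("detect_threshold_mv", 0.0)
    _diag(not -40 < thr < 40,
          "simulation: detect_threshold_mv outside (-40, 40)", diags)

    srch = doc.get("search", {}) or {}
    _diag(srch.get("tolerance", 0.02) <= 0, "search: tolerance must be positive", diags)

    for c in doc.get("cells", ["bc", "rgc"]):
        _diag(c not in ("bc", "rgc"), f"cells: unknown cell {c!r}", diags)
    for e in (doc.get("electrodes", {}) or {}).get("configs", ["TES1", "TES2"]):
        _diag(e not in ("TES1", "TES2"), f"electrodes: unknown preset {e!r}", diags)
    wf = doc.get("waveforms", {}) or {}
    for k in wf.get("kinds", ["biphasic"]):
        _diag(k not in ("biphasic", "monophasic"),
              f"waveforms: unknown kind {k!r}", diags)
    durs = wf.get("durations_ms", list(DEFAULT_DURATIONS_MS))
    _diag(any(d <= 0 for d in durs), "waveforms: durations must be positive", diags)
    _diag(list(durs) != sorted(durs), "waveforms: durations must be increasing", diags)

    saf = doc.get("safety", {}) or {}
    _diag(saf.get("phase_ms", 10.0) <= 0, "safety: phase_ms must be positive", diags)
    _diag(not 0 < saf.get("contact_fraction", 1.0) <= 1,
          "safety: contact_fraction must be in (0, 1]", diags)
    return diags


def load_experiment(source) -> ExperimentConfig:
    """Load and validate a config file (or dict) into an ExperimentConfig."""
    if isinstance(source, (str, Path)):
        doc = yaml.safe_load(Path(source).read_text()) or {}
    else:
        doc = source or {}
    diags = validate_config(doc)
    if diags:
        raise ValueError("invalid config:\n  " + "\n  ".join(diags))

    g = dict(doc.get("grid", {}) or {})
    tissues = doc.get("tissues")
    if tissues:
        g["resistivities"] = dict(tissues)
    grid_cfg = HeadEyeConfig(**g)

    el = doc.get("electrodes", {}) or {}
    wf = doc.get("waveforms", {}) or {}
    srch = doc.get("search", {}) or {}
    sim = doc.get("simulation", {}) or {}
    saf = doc.get("safety", {}) or {}
    out = doc.get("output", {}) or {}
    kin = doc.get("kinetics", {}) or {}

    return ExperimentConfig(
        grid=grid_cfg,
        electrode_configs=tuple(el.get("configs", ("TES1", "TES2"))),
        ring_diameter_mm=float(el.get("ring_diameter_mm", 3.0)),
        needle_exposed_mm=float(el.get("needle_exposed_mm", 2.0)),
        cells=tuple(doc.get("cells", ("bc", "rgc"))),
        kinetics_paths=dict(kin),
        waveform_kinds=tuple(wf.get("kinds", ("biphasic",))),
        durations_ms=tuple(wf.get("durations_ms", DEFAULT_DURATIONS_MS)),
        search=ThresholdSearch(
            seed_ua=float(srch.get("seed_ua", 1000.0)),
            tolerance=float(srch.get("tolerance", 0.02)),
            cap_ua=float(srch.get("cap_ua", 1e8)),
        ),
        simulation=SimulationConfig(
            dt_ms=float(sim.get("dt_ms", 0.01)),
            settle_ms=float(sim.get("settle_ms", 400.0)),
            post_ms=float(sim.get("post_ms", 10.0)),
            detect_threshold_mv=float(sim.get("detect_threshold_mv", 0.0)),
        ),
        safety_amplitudes_ua=tuple(saf.get("amplitudes_ua",
                                           (20.0, 50.0, 100.0, 200.0, 300.0, 400.0))),
        safety_phase_ms=float(saf.get("phase_ms", 10.0)),
        safety_ring_inner_mm=float(saf.get("ring_inner_diameter_mm", 3.0)),
        safety_wire_mm=float(saf.get("wire_diameter_mm", 0.27)),
        safety_contact_fraction=float(saf.get("contact_fraction", 1.0)),
        safety_k_limit=float(saf.get("k_limit", 1.5)),
        output_dir=Path(out.get("directory", "retistim_out")),
        seed=int(doc.get("seed", 0)),
        stages=tuple(doc.get("stages", ("field", "thresholds", "safety"))),
        raw=doc,
    )


def bundled_config(name: str) -> dict:
    """Parsed bundled config ('ratio' or 'safety')."""
    text = (resources.files("retistim") / "data" / "configs" / f"{name}.yaml").read_text()
    return yaml.safe_load(text)


# -- pipeline -------------------------------------------------------------


def _electrodes(grid: VoxelGrid, cfg: ExperimentConfig, name: str):
    d = cfg.ring_diameter_mm * 1e-3
    if name == "TES1":
        return tes1_preset(grid, ring_diameter_m=d)
    if name == "TES2":
        return tes2_preset(grid, ring_diameter_m=d,
                           needle_exposed_m=cfg.needle_exposed_mm * 1e-3)
    raise ValueError(f"unknown electrode preset {name!r}")


def _build_cell(grid: VoxelGrid, cfg: ExperimentConfig, name: str) -> CellModel:
    kin_path = cfg.kinetics_paths.get(name)
    if name == "bc":
        kin = load_kinetics(kin_path) if kin_path else bc_kinetics()
        return CellModel(build_bc_cell(grid), kin)
    if name == "rgc":
        kin = load_kinetics(kin_path) if kin_path else rgc_kinetics()
        return CellModel(build_rgc_cell(grid), kin)
    raise ValueError(f"unknown cell {name!r}")


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary.

    Writes per-stage artifacts under ``cfg.output_dir``; any stage error
    aborts with the stage name while earlier outputs remain on disk.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(cfg.raw, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "stages": {},
    }
    rng = np.random.default_rng(cfg.seed)  # reserved for stochastic fixtures
    _ = rng

    stage = "setup"
    try:
        grid = build_head_eye_model(cfg.grid)
        solutions: dict[str, FieldSolution] = {}
        if "field" in cfg.stages or "thresholds" in cfg.stages:
            stage = "field"
            t0 = time.time()
            system = assemble_network(grid)
            for name in cfg.electrode_configs:
                pair = _electrodes(grid, cfg, name)
                sol = solve_unit_field(system, pair.stimulating, pair.returning)
                solutions[name] = sol
                save_field_hdf5(sol, outdir / f"field_{name.lower()}.h5")
            manifest["stages"]["field"] = {
                "runtime_s": round(time.time() - t0, 2),
                "residuals": {k: s.residual for k, s in solutions.items()},
            }

        if "thresholds" in cfg.stages:
            stage = "thresholds"
            t0 = time.time()
            rows = []
            curves: dict = {}
            for cell_name in cfg.cells:
                model = _build_cell(grid, cfg, cell_name)
                pts = model.cell.chain.midpoint_m
                for econf in cfg.electrode_configs:
                    ve = potential_at(solutions[econf], pts)
                    for kind in cfg.waveform_kinds:
                        curve = strength_duration(
                            model, ve, cfg.durations_ms, kind, econf,
                            config=cfg.simulation, search=cfg.search,
                        )
                        curves[cell_name, econf, kind] = curve
                        for d, thr in zip(curve.durations_ms, curve.thresholds_ua):
                            rows.append({"cell": cell_name, "config": econf,
                                         "waveform": kind, "duration_ms": d,
                                         "threshold_ua": thr})
            pd.DataFrame(rows).to_csv(outdir / "strength_duration.csv",
                                      index=False, float_format=FLOAT_FMT)
            ratio_rows = []
            if {"TES1", "TES2"} <= set(cfg.electrode_configs):
                for cell_name in cfg.cells:
                    for kind in cfg.waveform_kinds:
                        rc = threshold_ratio(curves[cell_name, "TES1", kind],
                                             curves[cell_name, "TES2", kind])
                        for d, r in zip(rc.durations_ms, rc.ratios):
                            ratio_rows.append({"cell": cell_name, "waveform": kind,
                                               "duration_ms": d,
                                               "ratio_tes1_tes2": r})
                pd.DataFrame(ratio_rows).to_csv(outdir / "threshold_ratio.csv",
                                                index=False, float_format=FLOAT_FMT)
            _plot_curves(curves, ratio_rows, outdir)
            manifest["stages"]["thresholds"] = {
                "runtime_s": round(time.time() - t0, 2),
                "n_thresholds": len(rows),
            }

        if "safety" in cfg.stages:
            stage = "safety"
            area = ring_electrode_area(cfg.safety_ring_inner_mm, cfg.safety_wire_mm,
                                       cfg.safety_contact_fraction)
            points = shannon_chart(cfg.safety_amplitudes_ua, cfg.safety_phase_ms, area)
            pd.DataFrame(
                [{"amplitude_ua": p.amplitude_ua, "charge_uc": p.charge_uc,
                  "density_uc_cm2": p.density_uc_cm2, "k": p.k} for p in points]
            ).to_csv(outdir / "shannon.csv", index=False, float_format=FLOAT_FMT)
            safe = max_safe_amplitude(cfg.safety_amplitudes_ua, cfg.safety_phase_ms,
                                      area, cfg.safety_k_limit)
            _plot_shannon(points, cfg.safety_k_limit, outdir)
            manifest["stages"]["safety"] = {
                "electrode_area_cm2": area,
                "max_safe_amplitude_ua": safe,
                "k_limit": cfg.safety_k_limit,
            }
    except Exception as e:
        raise RuntimeError(f"experiment failed in stage {stage!r}: {e}") from e

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _plot_curves(curves, ratio_rows, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for (cell, econf, kind), c in curves.items():
        axes[0].loglog(c.durations_ms, c.thresholds_ua, "o-",
                       label=f"{cell} {econf} {kind}")
    axes[0].set_xlabel("pulse duration (ms)")
    axes[0].set_ylabel("threshold (uA)")
    axes[0].set_title("strength-duration")
    axes[0].legend(fontsize=6)
    if ratio_rows:
        df = pd.DataFrame(ratio_rows)
        for (cell, kind), sub in df.groupby(["cell", "waveform"]):
            axes[1].semilogx(sub["duration_ms"], sub["ratio_tes1_tes2"], "o-",
                             label=f"{cell} {kind}")
        axes[1].axhline(1.0, color="k", lw=0.5)
        axes[1].set_xlabel("pulse duration (ms)")
        axes[1].set_ylabel("threshold ratio TES1/TES2")
        axes[1].set_yscale("log")
        axes[1].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(outdir / "curves.png", dpi=120)
    plt.close(fig)


def _plot_shannon(points, k_limit: float, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    q = np.array([p.charge_uc for p in points])
    d = np.array([p.density_uc_cm2 for p in points])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.loglog(q, d, "o", color="tab:blue")
    qq = np.logspace(np.log10(q.min() / 2), np.log10(q.max() * 2), 50)
    for k, color in ((k_limit, "tab:red"), (2.0, "tab:blue")):
        ax.loglog(qq, 10.0**k / qq, "-", color=color, lw=1, label=f"k = {k:g}")
    ax.set_xlabel("charge per phase (uC)")
    ax.set_ylabel("charge density per phase (uC/cm$^2$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "shannon.png", dpi=120)
    plt.close(fig)


# -- HDF5 export ----------------------------------------------------------


def save_grid_hdf5(grid: VoxelGrid, path) -> None:
    """Write labels, spacing, origin and the resistivity table."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=grid.labels, compression="gzip")
        f.attrs["spacing_m"] = grid.spacing
        f.attrs["origin_m"] = grid.origin
        tgrp = f.create_group("tissues")
        for tid, name in grid.tissue_names.items():
            tgrp.attrs[name] = (tid, grid.resistivity_table[tid])


def save_field_hdf5(solution: FieldSolution, path) -> None:
    """Write node potentials (V/A) plus solve metadata."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset(
            "potential_v_per_a",
            data=solution.potentials.reshape(solution.node_dims),
            compression="gzip",
        )
        f.attrs["spacing_m"] = solution.spacing
        f.attrs["origin_m"] = solution.origin
        f.attrs["residual"] = solution.residual
        f.attrs["reference_node"] = solution.reference_node
        f.create_dataset("source_nodes", data=solution.source_nodes)
        f.create_dataset("sink_nodes", data=solution.sink_nodes)
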