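"""Parametric head-eye voxel model and electrode-to-node mapping.

The volume conductor is a uniform voxel lattice: a layered spherical eye
(cornea cap, lens, vitreous, retina shell) embedded in a head block of
skin / fat / bone / muscle / brain compartments.  Nodes sit at voxel
corners (0-based indices); ``world = origin + index * spacing``.  Tissue
labels are only resistivity keys -- the admittance network depends on the
per-voxel resistivity alone.

Electrodes are not meshed as conductors: an electrode is the set of lattice
nodes nearest its metal surface, used as an equipotential current-injection
site.  Named presets:

* ``TES1`` -- stimulating ring on the temporal side of the eyeball, return
  ring on the nasal side (lateral stimulation).
* ``TES2`` -- stimulating ring on the cornea, needle return on the temporal
  side of the head (vertical stimulation, along the retinal depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "DEFAULT_RESISTIVITIES",
    "VoxelGrid",
    "HeadEyeConfig",
    "RingElectrode",
    "NeedleElectrode",
    "ElectrodePair",
    "build_head_eye_model",
    "place_electrode",
    "tes1_preset",
    "tes2_preset",
]

#: tissue resistivities of the rat head-eye model, ohm*m
DEFAULT_RESISTIVITIES: dict[str, float] = {
    "muscle": 4.82,
    "skin": 5000.0,
    "fat": 64.61,
    "bone_marrow": 762.95,
    "bone_cancellous": 12.67,
    "brain": 25.72,
    "vitreous": 0.666,
    "retina": 1.5,
    "lens": 3.15,
    "cornea": 2.4,
}


@dataclass
class VoxelGrid:
    """Labeled uniform voxel lattice with a tissue resistivity table.

    ``labels`` has shape (nx, ny, nz) of voxel tissue ids; nodes live at
    voxel corners so the node lattice has shape ``labels.shape + 1``.
    """

    labels: np.ndarray
    spacing: float  # m
    origin: np.ndarray  # (3,) m
    tissue_names: dict[int, str]
    resistivity_table: dict[int, float]  # ohm*m keyed by tissue id
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.origin = np.asarray(self.origin, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.resistivity_table)
        if missing:
            raise ValueError(f"labels without resistivity entry: {sorted(missing)}")
        if any(r <= 0 for r in self.resistivity_table.values()):
            raise ValueError("all resistivities must be positive")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def node_dims(self) -> tuple[int, int, int]:
        nx, ny, nz = self.labels.shape
        return (nx + 1, ny + 1, nz + 1)

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.node_dims
        return nx * ny * nz

    def node_world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (m) of node indices, shape (..., 3)."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_node(self, pos: np.ndarray) -> np.ndarray:
        """Nearest node index triple for world positions."""
        idx = np.rint((np.asarray(pos, dtype=float) - self.origin) / self.spacing)
        return idx.astype(int)

    def node_flat(self, idx: np.ndarray) -> np.ndarray:
        return np.ravel_multi_index(tuple(np.asarray(idx).T), self.node_dims)

    def node_resistivity(self) -> np.ndarray:
        """Per-node resistivity: each node takes the resistivity of its voxel
        (boundary nodes clipped to the nearest voxel)."""
        lut_size = max(self.resistivity_table) + 1
        lut = np.full(lut_size, np.nan)
        for tid, rho in self.resistivity_table.items():
            lut[tid] = rho
        nx, ny, nz = self.labels.shape
        ix = np.minimum(np.arange(nx + 1), nx - 1)
        iy = np.minimum(np.arange(ny + 1), ny - 1)
        iz = np.minimum(np.arange(nz + 1), nz - 1)
        return lut[self.labels[np.ix_(ix, iy, iz)]]

    def tissue_id(self, name: str) -> int:
        for tid, n in self.tissue_names.items():
            if n == name:
                return tid
        raise KeyError(name)

    def resistivity_of(self, name: str) -> float:
        return self.resistivity_table[self.tissue_id(name)]


@dataclass(frozen=True)
class HeadEyeConfig:
    """Geometry and resolution of the reduced head-eye model (mm units)."""

    domain_mm: float = 20.0
    spacing_mm: float = 0.2
    eye_diameter_mm: float = 6.3
    retina_thickness_mm: float = 0.2
    cornea_thickness_mm: float = 0.3
    cornea_half_angle_deg: float = 50.0
    lens_diameter_mm: float = 3.5
    lens_offset_mm: float = 0.9  # lens center anterior of the eye center
    skin_thickness_mm: float = 0.6
    fat_thickness_mm: float = 0.6
    bone_thickness_mm: float = 0.8
    brain_posterior_mm: float = 9.0  # brain occupies z < this plane
    resistivities: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESISTIVITIES)
    )

    @property
    def eye_radius_mm(self) -> float:
        return self.eye_diameter_mm / 2.0

    @property
    def eye_center_mm(self) -> np.ndarray:
        """Eye center: laterally centered, anterior pole at the +z face."""
        c = self.domain_mm / 2.0
        return np.array([c, c, self.domain_mm - self.eye_radius_mm])


def build_head_eye_model(config: HeadEyeConfig | None = None) -> VoxelGrid:
    """Construct the layered head-eye voxel model.

    Raises
    ------
    ValueError
        If the spacing exceeds the retina thickness (the retina shell would
        vanish) or the layer thicknesses exceed the eye radius.
    """
    cfg = config or HeadEyeConfig()
    if cfg.spacing_mm > cfg.retina_thickness_mm:
        raise ValueError(
            f"spacing {cfg.spacing_mm} mm exceeds retina thickness "
            f"{cfg.retina_thickness_mm} mm: retina shell would vanish"
        )
    R = cfg.eye_radius_mm
    if cfg.retina_thickness_mm + cfg.cornea_thickness_mm >= R:
        raise ValueError("eye layer thicknesses exceed the eye radius")
    if cfg.lens_diameter_mm / 2.0 + cfg.lens_offset_mm >= R - cfg.cornea_thickness_mm:
        raise ValueError("lens protrudes into the cornea shell")

    names = sorted(cfg.resistivities)
    tid = {n: i + 1 for i, n in enumerate(names)}
    needed = {"muscle", "skin", "fat", "brain", "vitreous", "retina", "lens", "cornea"}
    missing = needed - set(tid)
    if missing:
        raise ValueError(f"config tissues missing required entries: {sorted(missing)}")

    h = cfg.spacing_mm
    n = int(round(cfg.domain_mm / h))
    # voxel-center coordinates in mm
    ax = (np.arange(n) + 0.5) * h
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")

    labels = np.full((n, n, n), tid["muscle"], dtype=np.int16)

    # head shells, from the domain boundary inward: skin, fat, bone
    d_face = np.minimum.reduce(
        [X, Y, Z, cfg.domain_mm - X, cfg.domain_mm - Y, cfg.domain_mm - Z]
    )
    t_sk, t_ft, t_bn = cfg.skin_thickness_mm, cfg.fat_thickness_mm, cfg.bone_thickness_mm
    if "bone_cancellous" in tid:
        labels[d_face < t_sk + t_ft + t_bn] = tid["bone_cancellous"]
    labels[d_face < t_sk + t_ft] = tid["fat"]
    labels[d_face < t_sk] = tid["skin"]

    # brain block in the posterior interior
    interior = d_face >= t_sk + t_ft + t_bn
    labels[interior & (Z < cfg.brain_posterior_mm)] = tid["brain"]

    # layered eye overrides everything it covers
    ec = cfg.eye_center_mm
    dx, dy, dz = X - ec[0], Y - ec[1], Z - ec[2]
    d = np.sqrt(dx * dx + dy * dy + dz * dz)
    inside = d < R
    # polar angle from the anterior (+z) eye axis
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = np.where(d > 0, dz / np.maximum(d, 1e-12), 1.0)
    cap = cos_theta >= np.cos(np.deg2rad(cfg.cornea_half_angle_deg))

    labels[inside] = tid["vitreous"]
    shell_ret = inside & (d >= R - cfg.retina_thickness_mm) & ~cap
    shell_cor = inside & (d >= R - cfg.cornea_thickness_mm) & cap
    labels[shell_ret] = tid["retina"]
    labels[shell_cor] = tid["cornea"]
    lc = ec + np.array([0.0, 0.0, cfg.lens_offset_mm])
    dl = np.sqrt((X - lc[0]) ** 2 + (Y - lc[1]) ** 2 + (Z - lc[2]) ** 2)
    labels[(dl < cfg.lens_diameter_mm / 2.0) & inside & ~shell_ret & ~shell_cor] = tid[
        "lens"
    ]

    _seal_eye_shell(labels, tid, cap)

    present = set(np.unique(labels).tolist())
    grid = VoxelGrid(
        labels=labels,
        spacing=h * 1e-3,
        origin=np.zeros(3),
        tissue_names={i: nm for nm, i in tid.items() if i in present},
        resistivity_table={
            i: float(cfg.resistivities[nm]) for nm, i in tid.items() if i in present
        },
        meta={
            "eye_center_m": (ec * 1e-3).tolist(),
            "eye_radius_m": R * 1e-3,
            "config": cfg,
        },
    )
    return grid


def _seal_eye_shell(labels: np.ndarray, tid: dict[str, int], cap: np.ndarray) -> None:
    """Relabel interior-eye voxels that touch extra-ocular tissue so the
    retina/cornea shell is watertight (at least one voxel thick everywhere)."""
    eye_ids = {tid[k] for k in ("vitreous", "lens", "retina", "cornea")}
    inner_ids = {tid["vitreous"], tid["lens"]}
    is_eye = np.isin(labels, list(eye_ids))
    is_inner = np.isin(labels, list(inner_ids))
    touches_out = np.zeros_like(is_inner)
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(is_eye, shift, axis=axis)
            # domain edge counts as outside
            sl = [slice(None)] * 3
            sl[axis] = 0 if shift == 1 else -1
            rolled[tuple(sl)] = False
            touches_out |= is_inner & ~rolled
    leak = touches_out
    labels[leak & cap] = tid["cornea"]
    labels[leak & ~cap] = tid["retina"]


def check_retina_watertight(grid: VoxelGrid) -> bool:
    """True if no vitreous/lens voxel is 6-adjacent to extra-ocular tissue."""
    tidmap = {v: k for k, v in grid.tissue_names.items()}
    eye_ids = [tidmap[k] for k in ("vitreous", "lens", "retina", "cornea") if k in tidmap]
    inner_ids = [tidmap[k] for k in ("vitreous", "lens") if k in tidmap]
    is_eye = np.isin(grid.labels, eye_ids)
    is_inner = np.isin(grid.labels, inner_ids)
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(is_eye, shift, axis=axis)
            sl = [slice(None)] * 3
            sl[axis] = 0 if shift == 1 else -1
            rolled[tuple(sl)] = False
            if np.any(is_inner & ~rolled):
                return False
    return True


# -- electrodes -----------------------------------------------------------


@dataclass(frozen=True)
class RingElectrode:
    """Ring (torus) electrode described by its centerline circle."""

    center_m: tuple[float, float, float]
    normal: tuple[float, float, float]
    ring_diameter_m: float
    wire_diameter_m: float = 270e-6
    role: str = "stimulating"


@dataclass(frozen=True)
class NeedleElectrode:
    """Straight needle with an exposed conducting shaft from the tip."""

    tip_m: tuple[float, float, float]
    direction: tuple[float, float, float]
    exposed_length_m: float
    role: str = "return"


ElectrodeSpec = RingElectrode | NeedleElectrode


@dataclass(frozen=True)
class ElectrodePair:
    """A named stimulating/return electrode placement on a grid."""

    name: str
    stimulating: np.ndarray  # flat node indices
    returning: np.ndarray

    def __post_init__(self):
        if len(self.stimulating) == 0 or len(self.returning) == 0:
            raise ValueError(f"{self.name}: empty electrode node set")
        if np.intersect1d(self.stimulating, self.returning).size:
            raise ValueError(f"{self.name}: stimulating and return node sets overlap")


def place_electrode(grid: VoxelGrid, spec: ElectrodeSpec) -> np.ndarray:
    """Map an electrode to the set of lattice nodes nearest its metal surface.

    Rings select nodes within half a spacing of the torus centerline circle;
    needles select nodes within half a spacing of the exposed shaft segment
    (always including the node nearest the tip).  Returns sorted flat node
    indices into the node lattice.
    """
    h = grid.spacing
    node_pts_axes = [
        grid.origin[k] + np.arange(grid.node_dims[k]) * h for k in range(3)
    ]

    def _nodes_in_box(lo, hi):
        idx = []
        for k in range(3):
            a = node_pts_axes[k]
            idx.append(np.nonzero((a >= lo[k] - h) & (a <= hi[k] + h))[0])
        if any(len(i) == 0 for i in idx):
            return None, None
        I, J, K = np.meshgrid(*idx, indexing="ij")
        pts = np.stack(
            [node_pts_axes[0][I], node_pts_axes[1][J], node_pts_axes[2][K]], axis=-1
        )
        triples = np.stack([I, J, K], axis=-1).reshape(-1, 3)
        return pts.reshape(-1, 3), triples

    if isinstance(spec, RingElectrode):
        c = np.asarray(spec.center_m, dtype=float)
        nrm = np.asarray(spec.normal, dtype=float)
        nrm = nrm / np.linalg.norm(nrm)
        R = spec.ring_diameter_m / 2.0
        lo, hi = c - (R + h), c + (R + h)
        pts, triples = _nodes_in_box(lo, hi)
        if pts is None:
            raise ValueError("ring electrode does not intersect the grid")
        v = pts - c
        axial = v @ nrm
        radial = np.linalg.norm(v - np.outer(axial, nrm), axis=1)
        dist = np.hypot(radial - R, axial)
        sel = dist <= h / 2.0
        if not np.any(sel):
            raise ValueError("ring electrode maps to an empty node set")
        flat = np.ravel_multi_index(tuple(triples[sel].T), grid.node_dims)
        return np.sort(flat)

    if isinstance(spec, NeedleElectrode):
        tip = np.asarray(spec.tip_m, dtype=float)
        d = np.asarray(spec.direction, dtype=float)
        d = d / np.linalg.norm(d)
        L = spec.exposed_length_m
        end = tip + d * L
        lo, hi = np.minimum(tip, end) - h, np.maximum(tip, end) + h
        pts, triples = _nodes_in_box(lo, hi)
        if pts is None:
            raise ValueError("needle electrode does not intersect the grid")
        v = pts - tip
        t = np.clip(v @ d, 0.0, L)
        dist = np.linalg.norm(v - np.outer(t, d), axis=1)
        sel = dist <= h / 2.0
        flat = set(
            np.ravel_multi_index(tuple(triples[sel].T), grid.node_dims).tolist()
        )
        # always include the node nearest the tip
        tip_idx = np.clip(grid.world_to_node(tip), 0, np.array(grid.node_dims) - 1)
        flat.add(int(np.ravel_multi_index(tuple(tip_idx), grid.node_dims)))
        return np.array(sorted(flat))

    raise TypeError(f"unknown electrode spec {type(spec).__name__}")


RING_DIAMETER_M = 3e-3  # stimulating ring inner diameter
RING_WIRE_M = 270e-6


def _eye_geometry(grid: VoxelGrid) -> tuple[np.ndarray, float]:
    try:
        ec = np.asarray(grid.meta["eye_center_m"], dtype=float)
        R = float(grid.meta["eye_radius_m"])
    except KeyError as e:
        raise ValueError("grid lacks head-eye metadata; build it with "
                         "build_head_eye_model") from e
    return ec, R


def tes1_preset(grid: VoxelGrid, ring_diameter_m: float = RING_DIAMETER_M) -> ElectrodePair:
    """TES1: stimulating ring on the temporal (+x) side of the eyeball,
    return ring on the nasal (-x) side."""
    ec, R = _eye_geometry(grid)
    r = ring_diameter_m / 2.0
    off = float(np.sqrt(R**2 - r**2))
    stim = RingElectrode(tuple(ec + [off, 0, 0]), (1, 0, 0), ring_diameter_m,
                         role="stimulating")
    ret = RingElectrode(tuple(ec + [-off, 0, 0]), (1, 0, 0), ring_diameter_m,
                        role="return")
    return ElectrodePair("TES1", place_electrode(grid, stim), place_electrode(grid, ret))


def tes2_preset(
    grid: VoxelGrid,
    ring_diameter_m: float = RING_DIAMETER_M,
    needle_exposed_m: float = 2e-3,
) -> ElectrodePair:
    """TES2: stimulating ring on the cornea, needle return placed on the
    temporal side of the head at eye height."""
    ec, R = _eye_geometry(grid)
    r = ring_diameter_m / 2.0
    off = float(np.sqrt(R**2 - r**2))
    stim = RingElectrode(tuple(ec + [0, 0, off]), (0, 0, 1), ring_diameter_m,
                         role="stimulating")
    xmax = grid.origin[0] + (grid.node_dims[0] - 1) * grid.spacing
    tip = (xmax - 5 * grid.spacing, ec[1], ec[2])
    ret = NeedleElectrode(tip, (-1, 0, 0), needle_exposed_m, role="return")
    return ElectrodePair("TES2", place_electrode(grid, stim), place_electrode(grid, ret))
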