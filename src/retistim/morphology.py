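"""Parametric morphologies for retinal neurons, plus SWC file I/O.

Two stylized cells are provided:

* a DB4-type spiking cone bipolar cell -- a five-region chain
  (dendrite -> soma -> axon -> presynaptic terminal -> terminal) oriented
  along the retina-depth axis;
* an A2-type retinal ganglion cell -- 20 um soma, planar dendritic arbor
  spanning 320 um, and a 1000 um axon subdivided into the axon hillock
  (AH), sodium-channel band (SOCB), narrow segment (NS) and distal axon
  (DA), running parallel to the retinal surface.

Morphologies live in a local micrometer frame: +z is the retina-depth axis
(pointing vitread, i.e. from the photoreceptor side toward the vitreous),
x/y span the retinal plane.  Section centerline points are (x, y, z) in um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable

import numpy as np

__all__ = [
    "Section",
    "Morphology",
    "BCParams",
    "RGCParams",
    "build_db4_bc",
    "build_a2_rgc",
    "read_swc",
    "write_swc",
]

BC_REGIONS = ("soma", "dendrite", "axon", "presynaptic_terminal", "terminal")
RGC_REGIONS = ("soma", "dendrite", "AH", "SOCB", "NS", "DA")


@dataclass(frozen=True)
class Section:
    """Straight frustum between two centerline points (um)."""

    region: str
    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    d0: float  # diameter at p0, um
    d1: float  # diameter at p1, um
    parent: int  # index of parent section, -1 for root (attached at parent p1)

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(np.subtract(self.p1, self.p0)))


@dataclass
class Morphology:
    """Connected tree of sections."""

    sections: list[Section]
    name: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        n_root = 0
        for i, s in enumerate(self.sections):
            if s.d0 <= 0 or s.d1 <= 0:
                raise ValueError(f"section {i}: non-positive diameter")
            if s.length_um <= 0:
                raise ValueError(f"section {i}: non-positive length")
            if s.parent == -1:
                n_root += 1
            elif not 0 <= s.parent < i:
                raise ValueError(f"section {i}: parent {s.parent} not an ancestor")
        if self.sections and n_root != 1:
            raise ValueError(f"morphology must have exactly one root, got {n_root}")

    @property
    def regions(self) -> set[str]:
        return {s.region for s in self.sections}

    def total_length_um(self) -> float:
        return sum(s.length_um for s in self.sections)

    def transformed(self, fn: Callable[[np.ndarray], np.ndarray]) -> "Morphology":
        """Apply a point transform (um -> um) to every centerline point."""
        out = [
            replace(s, p0=tuple(fn(np.asarray(s.p0, float))),
                    p1=tuple(fn(np.asarray(s.p1, float))))
            for s in self.sections
        ]
        return Morphology(out, name=self.name)


# -- DB4 spiking bipolar cell ---------------------------------------------


@dataclass(frozen=True)
class BCParams:
    """Section dimensions of the stylized DB4 bipolar cell (um).

    The chain runs along +z (retina depth, vitread); total cell height is
    the sum of the five section lengths (65 um by default).
    """

    dendrite_len: float = 10.0
    dendrite_diam: float = 1.5
    soma_len: float = 10.0
    soma_diam: float = 10.0
    axon_len: float = 35.0
    axon_diam: float = 1.0
    presyn_len: float = 5.0
    presyn_diam: float = 2.5
    terminal_len: float = 5.0
    terminal_diam: float = 1.5


def build_db4_bc(params: BCParams | None = None) -> Morphology:
    """Five-region bipolar-cell chain along the retina-depth axis."""
    p = params or BCParams()
    segs = [
        ("dendrite", p.dendrite_len, p.dendrite_diam),
        ("soma", p.soma_len, p.soma_diam),
        ("axon", p.axon_len, p.axon_diam),
        ("presynaptic_terminal", p.presyn_len, p.presyn_diam),
        ("terminal", p.terminal_len, p.terminal_diam),
    ]
    for region, L, d in segs:
        if L <= 0 or d <= 0:
            raise ValueError(f"{region}: non-positive length or diameter")
    sections: list[Section] = []
    z = 0.0
    for i, (region, L, d) in enumerate(segs):
        sections.append(
            Section(region, (0.0, 0.0, z), (0.0, 0.0, z + L), d, d, i - 1)
        )
        z += L
    return Morphology(sections, name="db4_bc")


# -- A2 retinal ganglion cell ---------------------------------------------


@dataclass(frozen=True)
class RGCParams:
    """Stylized A2 RGC geometry (um).

    The soma is an area-equivalent cylinder (diameter = length = 20 um).
    The axon regions AH -> SOCB -> NS -> DA must sum to the total axon
    length; the AH tapers 2 -> 1 um.  The planar dendritic arbor is a
    symmetric bifurcating tree whose tip-to-tip span equals
    ``dendritic_field_um``.
    """

    soma_diam: float = 20.0
    total_axon_um: float = 1000.0
    ah_len: float = 40.0
    socb_len: float = 40.0
    ns_len: float = 90.0
    da_len: float = 830.0
    ah_diam: tuple[float, float] = (2.0, 1.0)
    socb_diam: float = 1.0
    ns_diam: float = 0.4
    da_diam: float = 1.0
    dendritic_field_um: float = 320.0
    dend_primary_len: float = 60.0
    dend_primary_diam: float = 2.5
    dend_child_diam: float = 1.5
    dend_child_angle_deg: float = 40.0


def build_a2_rgc(params: RGCParams | None = None) -> Morphology:
    """Soma + planar bifurcating dendritic arbor + four-region axon.

    The axon runs along +x (parallel to the retinal surface); the arbor
    spans the y axis.  Raises if the axon segment lengths do not sum to the
    total axon length.
    """
    p = params or RGCParams()
    seg_sum = p.ah_len + p.socb_len + p.ns_len + p.da_len
    if not math.isclose(seg_sum, p.total_axon_um, rel_tol=1e-9):
        raise ValueError(
            f"axon segments sum to {seg_sum} um, expected {p.total_axon_um} um"
        )

    sections: list[Section] = []
    r_soma = p.soma_diam / 2.0
    # soma: area-equivalent cylinder along x, centered at the origin
    sections.append(
        Section("soma", (-r_soma, 0, 0), (r_soma, 0, 0), p.soma_diam, p.soma_diam, -1)
    )
    soma_idx = 0

    # dendritic arbor: two primaries along +/-y, each bifurcating once; the
    # child length is chosen so the tip-to-tip span equals the field size
    ang = math.radians(p.dend_child_angle_deg)
    half_span = p.dendritic_field_um / 2.0
    child_len = (half_span - p.dend_primary_len) / math.cos(ang)
    if child_len <= 0:
        raise ValueError("dendritic field smaller than the primary dendrite")
    for sy in (+1.0, -1.0):
        prim_end = (0.0, sy * p.dend_primary_len, 0.0)
        sections.append(
            Section("dendrite", (0.0, 0.0, 0.0), prim_end,
                    p.dend_primary_diam, p.dend_primary_diam, soma_idx)
        )
        prim_idx = len(sections) - 1
        for sx in (+1.0, -1.0):
            tip = (
                sx * child_len * math.sin(ang),
                sy * (p.dend_primary_len + child_len * math.cos(ang)),
                0.0,
            )
            sections.append(
                Section("dendrite", prim_end, tip,
                        p.dend_child_diam, p.dend_child_diam, prim_idx)
            )

    # axon along +x from the soma edge
    x = r_soma
    axon_segs = [
        ("AH", p.ah_len, p.ah_diam[0], p.ah_diam[1]),
        ("SOCB", p.socb_len, p.socb_diam, p.socb_diam),
        ("NS", p.ns_len, p.ns_diam, p.ns_diam),
        ("DA", p.da_len, p.da_diam, p.da_diam),
    ]
    parent = soma_idx
    for region, L, d0, d1 in axon_segs:
        sections.append(Section(region, (x, 0, 0), (x + L, 0, 0), d0, d1, parent))
        parent = len(sections) - 1
        x += L
    return Morphology(sections, name="a2_rgc")


# -- SWC I/O ---------------------------------------------------------------

#: default SWC structure-type -> region-tag mapping
SWC_TYPE_MAP = {1: "soma", 2: "axon", 3: "dendrite", 4: "dendrite"}


def read_swc(path: str | Path, type_map: dict[int, str] | None = None) -> Morphology:
    """Read a standard 7-column SWC morphology.

    Columns: id, structure type, x, y, z, radius, parent (1-based ids,
    parent -1 for the root).  Each non-root point becomes one section from
    its parent's position to its own, with diameter twice the point radius.
    """
    tmap = SWC_TYPE_MAP if type_map is None else type_map
    pts: dict[int, tuple[int, float, float, float, float, int]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        if len(f) != 7:
            raise ValueError(f"{path}:{ln}: expected 7 columns, got {len(f)}")
        pid, typ = int(f[0]), int(f[1])
        x, y, z, r = (float(v) for v in f[2:6])
        parent = int(f[6])
        if pid in pts:
            raise ValueError(f"{path}:{ln}: duplicate point id {pid}")
        if typ not in tmap:
            raise ValueError(f"{path}:{ln}: unmapped SWC structure type {typ}")
        pts[pid] = (typ, x, y, z, r, parent)

    # cycle / ordering check via iterative root walk
    order: list[int] = []
    index_of: dict[int, int] = {}
    seen: set[int] = set()
    for pid in pts:
        chain = []
        q = pid
        while q != -1 and q not in seen:
            if q not in pts:
                raise ValueError(f"SWC parent {q} does not exist")
            chain.append(q)
            q = pts[q][5]
            if q in chain:
                raise ValueError(f"cyclic parent links at point {q}")
        for q in reversed(chain):
            seen.add(q)
            index_of[q] = len(order)
            order.append(q)

    roots = [pid for pid in pts if pts[pid][5] == -1]
    if len(roots) != 1:
        raise ValueError(f"expected a single SWC root, found {len(roots)}")
    root = roots[0]

    sections: list[Section] = []
    sec_of_point: dict[int, int] = {root: -1}
    for pid in order:
        typ, x, y, z, r, parent = pts[pid]
        if parent == -1:
            # represent the root soma point as a diameter-length cylinder
            sections.append(
                Section(tmap[typ], (x - r, y, z), (x + r, y, z), 2 * r, 2 * r, -1)
            )
            sec_of_point[pid] = 0
            continue
        ptyp, px, py, pz, pr, _ = pts[parent]
        sections.append(
            Section(tmap[typ], (px, py, pz), (x, y, z), 2 * r, 2 * r,
                    sec_of_point[parent])
        )
        sec_of_point[pid] = len(sections) - 1
    return Morphology(sections, name=Path(path).stem)


def write_swc(morph: Morphology, path: str | Path,
              region_types: dict[str, int] | None = None) -> None:
    """Write a morphology as SWC (one point per section end)."""
    rmap = {v: k for k, v in SWC_TYPE_MAP.items()} if region_types is None else region_types
    lines = ["# id type x y z radius parent"]
    # root soma point reconstructed from the root section midpoint
    root = morph.sections[0]
    mid = (np.asarray(root.p0) + np.asarray(root.p1)) / 2.0
    lines.append(
        f"1 {rmap.get(root.region, 0)} {mid[0]:.6g} {mid[1]:.6g} {mid[2]:.6g} "
        f"{root.d0 / 2:.6g} -1"
    )
    pid_of_sec = {0: 1}
    next_id = 2
    for i, s in enumerate(morph.sections[1:], start=1):
        parent_pid = pid_of_sec[s.parent] if s.parent >= 0 else 1
        lines.append(
            f"{next_id} {rmap.get(s.region, 0)} {s.p1[0]:.6g} {s.p1[1]:.6g} "
            f"{s.p1[2]:.6g} {s.d1 / 2:.6g} {parent_pid}"
        )
        pid_of_sec[i] = next_id
        next_id += 1
    Path(path).write_text("\n".join(lines) + "\n")
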