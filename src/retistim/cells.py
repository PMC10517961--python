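"""Discretization of morphologies into compartments and channel assignment.

``compartmentalize`` splits every section into compartments no longer than
a maximum length, computing lateral membrane areas (pi * d * L, frustum
rule for tapered sections) and per-compartment axial resistances
R = Ri * L / (pi * r0 * r1).  The resistance between two coupled
compartments is the series half-resistance R_i/2 + R_j/2, so a uniform
cylinder split into n compartments keeps its end-to-end resistance.

``ChannelTable`` holds region x channel maximum conductance densities; the
shipped defaults reproduce the printed DB4 bipolar-cell densities
(mS/cm^2) and A2-RGC densities (S/cm^2, converted internally), including
the derived rows g_K,A = 3*g_K and g_K,Ca = 0.004*g_K.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping

import numpy as np
import yaml

from .morphology import Morphology, build_a2_rgc, build_db4_bc

__all__ = [
    "CompartmentChain",
    "ChannelTable",
    "Cell",
    "compartmentalize",
    "assign_channels",
    "bc_channel_table",
    "rgc_channel_table",
    "load_channel_table",
    "RetinalFrame",
    "build_bc_cell",
    "build_rgc_cell",
]

#: membrane capacitance (uF/cm^2) and intracellular resistivity (ohm*cm)
BC_CM_UF_CM2 = 1.0
BC_RI_OHM_CM = 100.0
RGC_CM_UF_CM2 = 1.0
RGC_RI_OHM_CM = 110.0

#: default maximum compartment lengths (um); both are far below the
#: electrotonic space constant of the thinnest neurite (> 400 um)
BC_MAX_COMPARTMENT_UM = 5.0
RGC_MAX_COMPARTMENT_UM = 20.0


@dataclass
class CompartmentChain:
    """Discretized cell: per-compartment geometry plus passive constants."""

    regions: np.ndarray  # (n,) str
    area_cm2: np.ndarray  # (n,) lateral membrane area
    axial_r_ohm: np.ndarray  # (n,) compartment's own axial resistance
    parent: np.ndarray  # (n,) int, -1 for root
    midpoint_m: np.ndarray  # (n, 3) world positions
    length_um: np.ndarray
    cm_uf_cm2: float
    ri_ohm_cm: float
    name: str = ""

    @property
    def n(self) -> int:
        return len(self.regions)

    def coupling_conductance_ms(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(child, parent, g_mS) triples: g = 1 / (R_c/2 + R_p/2), in mS."""
        child = np.nonzero(self.parent >= 0)[0]
        par = self.parent[child]
        r = 0.5 * (self.axial_r_ohm[child] + self.axial_r_ohm[par])
        return child, par, 1000.0 / r

    def compartments_in(self, region: str) -> np.ndarray:
        return np.nonzero(self.regions == region)[0]


def compartmentalize(
    morph: Morphology,
    max_compartment_um: float,
    cm_uf_cm2: float,
    ri_ohm_cm: float,
    point_transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> CompartmentChain:
    """Split sections into compartments of length <= ``max_compartment_um``.

    ``point_transform`` maps local centerline points (um) to world meters;
    the default treats local coordinates as already metric (um * 1e-6).
    """
    if max_compartment_um <= 0:
        raise ValueError("max_compartment_um must be positive")
    to_world = point_transform or (lambda p: p * 1e-6)

    regions: list[str] = []
    areas: list[float] = []
    axial: list[float] = []
    parent: list[int] = []
    mids: list[np.ndarray] = []
    lengths: list[float] = []
    last_comp_of_sec: list[int] = []

    for s in morph.sections:
        L = s.length_um
        nseg = max(1, math.ceil(L / max_compartment_um))
        p0, p1 = np.asarray(s.p0, float), np.asarray(s.p1, float)
        sec_parent = last_comp_of_sec[s.parent] if s.parent >= 0 else -1
        for k in range(nseg):
            a, b = k / nseg, (k + 1) / nseg
            d_a = s.d0 + (s.d1 - s.d0) * a
            d_b = s.d0 + (s.d1 - s.d0) * b
            l_um = L / nseg
            # frustum lateral area, um^2 -> cm^2
            area = math.pi * l_um * (d_a + d_b) / 2.0 * 1e-8
            # axial resistance of a frustum: Ri * L / (pi r_a r_b), um -> cm
            r_a_cm, r_b_cm = d_a / 2 * 1e-4, d_b / 2 * 1e-4
            r_ax = ri_ohm_cm * (l_um * 1e-4) / (math.pi * r_a_cm * r_b_cm)
            mid_local = p0 + (p1 - p0) * (a + b) / 2.0
            regions.append(s.region)
            areas.append(area)
            axial.append(r_ax)
            parent.append(sec_parent if k == 0 else len(regions) - 2)
            mids.append(np.asarray(to_world(mid_local), float))
            lengths.append(l_um)
        last_comp_of_sec.append(len(regions) - 1)

    return CompartmentChain(
        regions=np.array(regions),
        area_cm2=np.array(areas),
        axial_r_ohm=np.array(axial),
        parent=np.array(parent, dtype=int),
        midpoint_m=np.vstack(mids),
        length_um=np.array(lengths),
        cm_uf_cm2=cm_uf_cm2,
        ri_ohm_cm=ri_ohm_cm,
        name=morph.name,
    )


# -- channel tables --------------------------------------------------------


@dataclass
class ChannelTable:
    """Region x channel maximum conductance densities in mS/cm^2.

    ``leak_ms_cm2``/``leak_erev_mv`` describe the uniform leak; absent
    (region, channel) entries mean zero density.
    """

    densities: dict[str, dict[str, float]]  # region -> channel -> mS/cm^2
    leak_ms_cm2: float
    leak_erev_mv: float
    name: str = ""

    @property
    def channels(self) -> list[str]:
        seen: dict[str, None] = {}
        for row in self.densities.values():
            for ch in row:
                seen.setdefault(ch)
        return list(seen)

    def density(self, region: str, channel: str) -> float:
        if region not in self.densities:
            raise KeyError(f"unknown region tag {region!r}")
        return self.densities[region].get(channel, 0.0)


_EXPR = re.compile(r"^\s*([0-9.eE+-]+)\s*\*\s*(\w+)\s*$")


def _resolve_entry(val, region_row: Mapping[str, float]) -> float:
    """Resolve a numeric entry or a '<factor> * <channel>' expression."""
    if isinstance(val, (int, float)):
        return float(val)
    m = _EXPR.match(str(val))
    if not m:
        raise ValueError(f"cannot parse channel-table entry {val!r}")
    factor, ref = float(m.group(1)), m.group(2)
    if ref not in region_row:
        raise ValueError(f"expression {val!r} references unknown channel {ref!r}")
    return factor * float(region_row[ref])


def load_channel_table(source) -> ChannelTable:
    """Load a channel table from YAML (path, file object or parsed dict).

    Schema: ``units`` (mS/cm2 or S/cm2), ``regions`` (list), ``channels``
    (channel -> region -> density or expression), ``leak`` (density_ms_cm2,
    erev_mv).  Expressions like ``3 * g_K`` are resolved per region.
    """
    if isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        doc = yaml.safe_load(open(source))
    unit = doc.get("units", "mS/cm2")
    scale = {"mS/cm2": 1.0, "S/cm2": 1000.0}[unit]
    regions = list(doc["regions"])
    dens: dict[str, dict[str, float]] = {r: {} for r in regions}
    # numeric entries first so expressions can reference them
    items = sorted(
        doc["channels"].items(),
        key=lambda kv: any(isinstance(v, str) for v in (
            kv[1].values() if isinstance(kv[1], dict) else [kv[1]])),
    )
    for ch, row in items:
        if isinstance(row, dict):
            per_region = row
        else:
            per_region = {r: row for r in regions}
        for r, val in per_region.items():
            if r not in dens:
                raise ValueError(f"channel {ch}: unknown region {r!r}")
            v = _resolve_entry(val, dens[r])
            if v != 0.0:
                dens[r][ch] = v
    # scale to mS/cm^2 only after expressions are resolved in table units
    for row_ in dens.values():
        for ch in row_:
            row_[ch] *= scale
    leak = doc["leak"]
    return ChannelTable(
        densities=dens,
        leak_ms_cm2=float(leak["density_ms_cm2"]),
        leak_erev_mv=float(leak["erev_mv"]),
        name=doc.get("name", ""),
    )


def _data_text(fname: str) -> str:
    return (resources.files("retistim") / "data" / fname).read_text()


def bc_channel_table() -> ChannelTable:
    """Shipped DB4 spiking bipolar-cell densities (printed table, mS/cm^2)."""
    return load_channel_table(yaml.safe_load(_data_text("channels_bc.yaml")))


def rgc_channel_table() -> ChannelTable:
    """Shipped A2-RGC densities (printed table, S/cm^2)."""
    return load_channel_table(yaml.safe_load(_data_text("channels_rgc.yaml")))


@dataclass
class Cell:
    """A channelized, placed cell ready for simulation."""

    chain: CompartmentChain
    channel_names: list[str]
    gbar_ms_cm2: np.ndarray  # (n_comp, n_chan)
    leak_ms_cm2: np.ndarray  # (n_comp,)
    leak_erev_mv: float
    detection_region: str
    name: str = ""

    @property
    def n(self) -> int:
        return self.chain.n

    @property
    def detection_indices(self) -> np.ndarray:
        idx = self.chain.compartments_in(self.detection_region)
        if idx.size == 0:
            raise ValueError(f"no compartments tagged {self.detection_region!r}")
        return idx

    @property
    def detection_compartment(self) -> int:
        idx = self.detection_indices
        return int(idx[len(idx) // 2])


def assign_channels(
    chain: CompartmentChain,
    table: ChannelTable,
    detection_region: str,
    name: str = "",
) -> Cell:
    """Attach region-wise channel densities to every compartment."""
    unknown = set(np.unique(chain.regions)) - set(table.densities)
    if unknown:
        raise KeyError(f"region tags missing from channel table: {sorted(unknown)}")
    channels = table.channels
    gbar = np.zeros((chain.n, len(channels)))
    for i, region in enumerate(chain.regions):
        for j, ch in enumerate(channels):
            gbar[i, j] = table.density(region, ch)
    leak = np.full(chain.n, table.leak_ms_cm2)
    return Cell(
        chain=chain,
        channel_names=channels,
        gbar_ms_cm2=gbar,
        leak_ms_cm2=leak,
        leak_erev_mv=table.leak_erev_mv,
        detection_region=detection_region,
        name=name or chain.name,
    )


def cell_to_json(cell: Cell, path=None) -> dict:
    """Serializable description of a channelized cell: per-compartment
    region, area, axial resistance, parent, midpoint and densities.
    Writes JSON to ``path`` when given."""
    import json

    chain = cell.chain
    doc = {
        "name": cell.name,
        "cm_uf_cm2": chain.cm_uf_cm2,
        "ri_ohm_cm": chain.ri_ohm_cm,
        "leak_erev_mv": cell.leak_erev_mv,
        "channels": cell.channel_names,
        "compartments": [
            {
                "region": str(chain.regions[i]),
                "area_cm2": float(chain.area_cm2[i]),
                "axial_r_ohm": float(chain.axial_r_ohm[i]),
                "parent": int(chain.parent[i]),
                "midpoint_m": [float(x) for x in chain.midpoint_m[i]],
                "gbar_ms_cm2": [float(g) for g in cell.gbar_ms_cm2[i]],
                "leak_ms_cm2": float(cell.leak_ms_cm2[i]),
            }
            for i in range(chain.n)
        ],
    }
    if path is not None:
        from pathlib import Path

        Path(path).write_text(json.dumps(doc, indent=1))
    return doc


# -- placement in the curved retina ---------------------------------------


@dataclass(frozen=True)
class RetinalFrame:
    """Curvilinear frame following the spherical retina.

    Local morphology coordinates (um) are mapped to world meters with
    ``x`` = arc length along the temporal direction, ``y`` = arc length
    along the orthogonal tangential direction, and ``z`` = depth below the
    outer retinal surface increasing vitread.  ``anchor_arc_um`` offsets
    the frame origin from the posterior pole toward the temporal side.
    """

    eye_center_m: tuple[float, float, float]
    eye_radius_m: float
    anchor_arc_um: float = 200.0
    anchor_depth_um: float = 0.0  # local z = 0 maps to this depth

    def world(self, p_um: np.ndarray) -> np.ndarray:
        p = np.asarray(p_um, float)
        depth_m = (self.anchor_depth_um + p[2]) * 1e-6
        r = self.eye_radius_m - depth_m
        alpha = (self.anchor_arc_um + p[0]) * 1e-6 / r
        beta = p[1] * 1e-6 / r
        # unit normal: posterior pole direction (-z) rotated by alpha about
        # y (temporal) and beta about x
        n = np.array(
            [
                math.sin(alpha) * math.cos(beta),
                math.sin(beta),
                -math.cos(alpha) * math.cos(beta),
            ]
        )
        return np.asarray(self.eye_center_m) + r * n


#: retinal depths (um below the outer surface) of the model cells
BC_DENDRITE_DEPTH_UM = 70.0  # outer plexiform layer
RGC_SOMA_DEPTH_UM = 160.0  # ganglion cell layer
RGC_AXON_DEPTH_UM = 175.0  # nerve fiber layer


def _frame_from_grid(grid, anchor_arc_um: float | None) -> RetinalFrame:
    ec = grid.meta["eye_center_m"]
    R = grid.meta["eye_radius_m"]
    arc = grid.spacing * 1e6 if anchor_arc_um is None else anchor_arc_um
    return RetinalFrame(tuple(ec), R, anchor_arc_um=arc)


def build_bc_cell(
    grid=None,
    params=None,
    table: ChannelTable | None = None,
    max_compartment_um: float = BC_MAX_COMPARTMENT_UM,
    anchor_arc_um: float | None = None,
) -> Cell:
    """DB4 bipolar cell compartmentalized and placed radially in the retina.

    The cell spans the retina depth (dendrite at the outer plexiform layer,
    terminal in the inner plexiform layer).  Without a grid the cell stays
    in its local frame (useful for isolated-cell tests).
    """
    morph = build_db4_bc(params)
    if grid is not None:
        frame = _frame_from_grid(grid, anchor_arc_um)
        frame = RetinalFrame(
            frame.eye_center_m, frame.eye_radius_m, frame.anchor_arc_um,
            anchor_depth_um=BC_DENDRITE_DEPTH_UM,
        )
        transform = frame.world
    else:
        transform = None
    chain = compartmentalize(
        morph, max_compartment_um, BC_CM_UF_CM2, BC_RI_OHM_CM, transform
    )
    return assign_channels(chain, table or bc_channel_table(),
                           detection_region="axon", name="db4_bc")


def build_rgc_cell(
    grid=None,
    params=None,
    table: ChannelTable | None = None,
    max_compartment_um: float = RGC_MAX_COMPARTMENT_UM,
    anchor_arc_um: float | None = None,
) -> Cell:
    """A2 RGC compartmentalized and placed tangentially in the retina.

    Soma in the ganglion-cell layer; the axon follows the curved nerve
    fiber layer toward the temporal side.
    """
    morph = build_a2_rgc(params)
    if grid is not None:
        frame = _frame_from_grid(grid, anchor_arc_um)
        frame = RetinalFrame(
            frame.eye_center_m, frame.eye_radius_m, frame.anchor_arc_um,
            anchor_depth_um=RGC_SOMA_DEPTH_UM,
        )

        tr = frame.world
    else:
        tr = None
    chain = compartmentalize(
        morph, max_compartment_um, RGC_CM_UF_CM2, RGC_RI_OHM_CM, tr
    )
    return assign_channels(chain, table or rgc_channel_table(),
                           detection_region="DA", name="a2_rgc")
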