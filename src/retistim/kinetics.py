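"""Voltage-gated channel kinetics: rate-function registry and gating math.

The channel inventory (which channels exist where, at what density) is
fixed by the channel tables; the *kinetics* -- how each gate moves -- are
configuration, expressed as named parametric rate forms:

``exp_linear``   c + k*(V-v0) / (1 - exp(-(V-v0)/s))   (-> k*s at V=v0)
``exponential``  c + k*exp((V-v0)/s)
``sigmoid``      c + k / (1 + exp(-(V-v0)/s))
``gaussian``     c + k*exp(-((V-v0)/s)^2)
``constant``     c + k

Each gate is given either (alpha, beta) rate functions or (inf, tau)
directly; gates advance by the exponential-Euler closed form
``x <- x_inf + (x - x_inf) exp(-dt/tau)``.  The shipped registries follow
the Fohlmeister-Miller five-conductance retinal ganglion cell formulation
(Na, K, A-type K, Ca with a calcium pool and calcium-dependent K), with
h- and T-type currents from the retinal modeling literature, and an
HH-style spiking bipolar cell set (Na, fast/slow K, L-/T-type Ca, HCN).
Rates are per ms, potentials in mV.

Intracellular calcium follows a single-pool model

    d[Ca]/dt = -k_ca * I_Ca - ([Ca] - Ca_rest) / tau_ca

with [Ca] floored at a positive minimum; E_Ca follows the Nernst relation
from the pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "Rate",
    "GateSpec",
    "CaGateSpec",
    "ChannelSpec",
    "CaPoolParams",
    "KineticsSpec",
    "eval_rate",
    "gate_inf_tau",
    "gating_update",
    "ionic_current",
    "calcium_update",
    "bc_kinetics",
    "rgc_kinetics",
    "load_kinetics",
]

V_RANGE_MV = (-120.0, 60.0)  # validated voltage range


@dataclass(frozen=True)
class Rate:
    """One parametric rate function of membrane potential."""

    form: str
    k: float
    v0: float = 0.0
    s: float = 1.0
    c: float = 0.0

    def __call__(self, v_mv):
        return eval_rate(self, v_mv)


def eval_rate(rate: Rate, v_mv):
    v = np.asarray(v_mv, dtype=float)
    x = (v - rate.v0) / rate.s
    if rate.form == "exp_linear":
        # k*(V-v0)/(1-exp(-x)) with the removable singularity at x = 0
        denom = -np.expm1(-x)
        small = np.abs(x) < 1e-7
        val = rate.k * rate.s * np.where(
            small, 1.0 + x / 2.0, x / np.where(small, 1.0, denom)
        )
    elif rate.form == "exponential":
        val = rate.k * np.exp(x)
    elif rate.form == "sigmoid":
        val = rate.k / (1.0 + np.exp(-x))
    elif rate.form == "gaussian":
        val = rate.k * np.exp(-(x * x))
    elif rate.form == "constant":
        val = np.full_like(v, rate.k)
    else:
        raise ValueError(f"unknown rate form {rate.form!r}")
    out = val + rate.c
    return float(out) if np.ndim(v_mv) == 0 else out


@dataclass(frozen=True)
class GateSpec:
    """One activation/inactivation gate: exponent and rate functions."""

    exponent: int
    mode: str  # 'alphabeta' or 'inftau'
    f1: Rate  # alpha, or x_inf
    f2: Rate  # beta, or tau

    def inf_tau(self, v_mv):
        if self.mode == "alphabeta":
            a, b = eval_rate(self.f1, v_mv), eval_rate(self.f2, v_mv)
            tau = 1.0 / (a + b)
            return a * tau, tau
        inf = eval_rate(self.f1, v_mv)
        tau = eval_rate(self.f2, v_mv)
        return inf, tau


def gate_inf_tau(gate: GateSpec, v_mv):
    return gate.inf_tau(v_mv)


@dataclass(frozen=True)
class CaGateSpec:
    """Calcium-activated opening factor (Ca/kd)^p / (1 + (Ca/kd)^p)."""

    kd_mm: float = 1e-3
    power: float = 2.0

    def open_fraction(self, ca_mm):
        r = (np.asarray(ca_mm, dtype=float) / self.kd_mm) ** self.power
        return r / (1.0 + r)


@dataclass(frozen=True)
class ChannelSpec:
    """Kinetic description of one channel type."""

    name: str
    ion: str  # 'na' | 'k' | 'ca' | 'h'
    erev_mv: float | str  # number, or 'nernst_ca'
    gates: tuple[GateSpec, ...] = ()
    ca_gate: CaGateSpec | None = None


@dataclass(frozen=True)
class CaPoolParams:
    """Single-pool intracellular calcium dynamics."""

    k_mm_cm2_per_ua_ms: float = 1.55e-5  # influx scale (shell ~0.1 um)
    tau_ms: float = 20.0
    rest_mm: float = 1e-4
    floor_mm: float = 1e-6
    ca_out_mm: float = 1.8
    rt_over_2f_mv: float = 13.35  # RT/2F at 37 C
    fixed_eca_mv: float = 120.0  # fallback when no pool is simulated

    def nernst_eca_mv(self, ca_mm):
        return self.rt_over_2f_mv * np.log(self.ca_out_mm / np.asarray(ca_mm, float))


@dataclass(frozen=True)
class KineticsSpec:
    """Registry of channel kinetics plus calcium-pool parameters."""

    channels: Mapping[str, ChannelSpec]
    ca_pool: CaPoolParams = field(default_factory=CaPoolParams)
    name: str = ""

    def channel(self, name: str) -> ChannelSpec:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(f"channel {name!r} missing from kinetics registry "
                           f"{self.name!r}") from None

    def validate(self, v_grid: np.ndarray | None = None) -> None:
        """Check tau > 0 and inf in [0, 1] over the simulated voltage range."""
        v = (np.linspace(*V_RANGE_MV, 361) if v_grid is None else v_grid)
        for ch in self.channels.values():
            for g in ch.gates:
                inf, tau = g.inf_tau(v)
                if np.any(tau <= 0):
                    raise ValueError(f"{ch.name}: tau <= 0 in the voltage range")
                if np.any((inf < 0) | (inf > 1)):
                    raise ValueError(f"{ch.name}: x_inf outside [0, 1]")


# -- state-level operations ------------------------------------------------


def gating_update(x, v_mv, dt_ms: float, gate: GateSpec):
    """Advance gate values by the exponential-Euler closed form."""
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    if not np.all(np.isfinite(v_mv)):
        raise FloatingPointError("non-finite membrane potential in gating update")
    inf, tau = gate.inf_tau(v_mv)
    return inf + (np.asarray(x, float) - inf) * np.exp(-dt_ms / tau)


def channel_conductance(spec: ChannelSpec, gbar_ms_cm2, gates, ca_mm=None):
    """Open conductance density (mS/cm^2) from gate values.

    ``gates`` is a sequence of per-gate arrays aligned with ``spec.gates``.
    """
    g = np.asarray(gbar_ms_cm2, dtype=float).copy()
    for gs, x in zip(spec.gates, gates):
        g = g * np.asarray(x) ** gs.exponent
    if spec.ca_gate is not None:
        if ca_mm is None:
            raise ValueError(f"{spec.name}: calcium-gated channel needs [Ca]")
        g = g * spec.ca_gate.open_fraction(ca_mm)
    return g


def ionic_current(
    spec: ChannelSpec,
    gbar_ms_cm2,
    v_mv,
    gates,
    ca_mm=None,
    pool: CaPoolParams | None = None,
):
    """Channel current density in uA/cm^2 (outward positive)."""
    g = channel_conductance(spec, gbar_ms_cm2, gates, ca_mm)
    if spec.erev_mv == "nernst_ca":
        p = pool or CaPoolParams()
        e = p.nernst_eca_mv(ca_mm) if ca_mm is not None else p.fixed_eca_mv
    else:
        e = spec.erev_mv
    return g * (np.asarray(v_mv, float) - e)


def leak_current(g_leak_ms_cm2, e_leak_mv, v_mv):
    """Ohmic leak current density in uA/cm^2."""
    return np.asarray(g_leak_ms_cm2) * (np.asarray(v_mv, float) - e_leak_mv)


def calcium_update(ca_mm, i_ca_ua_cm2, dt_ms: float, pool: CaPoolParams):
    """Advance the calcium pool by the exponential-Euler closed form.

    With I_Ca frozen over the step the pool ODE is linear with steady state
    Ca_rest - k*tau*I_Ca and time constant tau.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    ca = np.asarray(ca_mm, dtype=float)
    target = pool.rest_mm - pool.k_mm_cm2_per_ua_ms * pool.tau_ms * np.asarray(
        i_ca_ua_cm2, float
    )
    new = target + (ca - target) * math.exp(-dt_ms / pool.tau_ms)
    return np.maximum(new, pool.floor_mm)


# -- registry I/O ----------------------------------------------------------


def _parse_rate(doc) -> Rate:
    return Rate(
        form=doc["form"],
        k=float(doc["k"]),
        v0=float(doc.get("v0", 0.0)),
        s=float(doc.get("s", 1.0)),
        c=float(doc.get("c", 0.0)),
    )


def load_kinetics(source) -> KineticsSpec:
    """Load a kinetics registry from YAML (path, file object or dict).

    Schema per channel: ``ion``, ``erev_mv`` (number or ``nernst_ca``),
    ``gates`` (list of ``{exponent, alpha, beta}`` or
    ``{exponent, inf, tau}`` with rate-form dicts), optional ``ca_gate``
    (``kd_mm``, ``power``); top-level ``ca_pool`` overrides pool defaults.
    """
    if isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        doc = yaml.safe_load(open(source))
    channels: dict[str, ChannelSpec] = {}
    for name, cdoc in doc["channels"].items():
        gates = []
        for gdoc in cdoc.get("gates", []):
            if "alpha" in gdoc:
                gates.append(GateSpec(int(gdoc["exponent"]), "alphabeta",
                                      _parse_rate(gdoc["alpha"]),
                                      _parse_rate(gdoc["beta"])))
            else:
                gates.append(GateSpec(int(gdoc["exponent"]), "inftau",
                                      _parse_rate(gdoc["inf"]),
                                      _parse_rate(gdoc["tau"])))
        ca_gate = None
        if "ca_gate" in cdoc:
            ca_gate = CaGateSpec(float(cdoc["ca_gate"]["kd_mm"]),
                                 float(cdoc["ca_gate"].get("power", 2.0)))
        channels[name] = ChannelSpec(
            name=name,
            ion=cdoc["ion"],
            erev_mv=(cdoc["erev_mv"] if cdoc["erev_mv"] == "nernst_ca"
                     else float(cdoc["erev_mv"])),
            gates=tuple(gates),
            ca_gate=ca_gate,
        )
    pool = CaPoolParams(**{k: float(v) for k, v in doc.get("ca_pool", {}).items()})
    spec = KineticsSpec(channels=channels, ca_pool=pool, name=doc.get("name", ""))
    spec.validate()
    return spec


def _load_data(fname: str) -> KineticsSpec:
    text = (resources.files("retistim") / "data" / fname).read_text()
    return load_kinetics(yaml.safe_load(text))


def bc_kinetics() -> KineticsSpec:
    """Shipped spiking bipolar-cell kinetics registry."""
    return _load_data("kinetics_bc.yaml")


def rgc_kinetics() -> KineticsSpec:
    """Shipped A2-RGC kinetics registry (Fohlmeister-Miller lineage)."""
    return _load_data("kinetics_rgc.yaml")
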