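"""Shannon electrode-safety analysis for stimulating electrodes.

The Shannon criterion bounds non-damaging stimulation by the empirical line

    log10(D) = k - log10(Q)

where ``Q`` is the charge per phase (uC), ``D`` the charge density per phase
(uC/cm^2) and ``k`` a damage parameter: k = 1.5 bounds the region where no
tissue damage has been observed, while k = 2 marks stimulation regimes where
damage occurs.  For a corneal ring electrode the geometric surface is a torus
of centerline radius R and wire radius r, area 4*pi^2*R*r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "ShannonPoint",
    "ring_electrode_area",
    "shannon_point",
    "shannon_chart",
    "max_safe_amplitude",
    "K_NO_DAMAGE",
    "K_DAMAGE",
]

#: damage-boundary parameters of the Shannon line
K_NO_DAMAGE = 1.5
K_DAMAGE = 2.0


@dataclass(frozen=True)
class ShannonPoint:
    """One stimulation operating point on the Shannon chart.

    Attributes
    ----------
    amplitude_ua : float
        Current amplitude in uA.
    phase_ms : float
        Single-phase duration in ms.
    charge_uc : float
        Charge per phase Q = I * t in uC.
    density_uc_cm2 : float
        Charge density per phase D = Q / area in uC/cm^2.
    k : float
        Shannon parameter log10(D) + log10(Q).
    """

    amplitude_ua: float
    phase_ms: float
    charge_uc: float
    density_uc_cm2: float
    k: float

    def is_safe(self, k_limit: float = K_NO_DAMAGE) -> bool:
        return self.k <= k_limit


def ring_electrode_area(
    inner_diameter_mm: float,
    wire_diameter_mm: float,
    contact_fraction: float = 1.0,
) -> float:
    """Geometric surface area of a ring (torus) electrode in cm^2.

    ``R = (inner_diameter + wire_diameter) / 2`` is the torus centerline
    radius and ``r = wire_diameter / 2`` the wire radius; the full torus
    surface is ``4 pi^2 R r``.  ``contact_fraction`` scales the area for
    electrodes only partially in contact with tissue.
    """
    if inner_diameter_mm <= 0 or wire_diameter_mm <= 0:
        raise ValueError("electrode dimensions must be positive")
    if not 0 < contact_fraction <= 1:
        raise ValueError("contact_fraction must be in (0, 1]")
    R_mm = (inner_diameter_mm + wire_diameter_mm) / 2.0
    r_mm = wire_diameter_mm / 2.0
    area_mm2 = 4.0 * math.pi**2 * R_mm * r_mm * contact_fraction
    return area_mm2 / 100.0  # mm^2 -> cm^2


def shannon_point(amplitude_ua: float, phase_ms: float, area_cm2: float) -> ShannonPoint:
    """Evaluate charge per phase, charge density and the Shannon k."""
    if amplitude_ua <= 0 or phase_ms <= 0 or area_cm2 <= 0:
        raise ValueError("amplitude, phase duration and area must be positive")
    q_uc = amplitude_ua * phase_ms * 1e-3  # uA * ms = nC; /1000 -> uC
    d = q_uc / area_cm2
    k = math.log10(d) + math.log10(q_uc)
    return ShannonPoint(amplitude_ua, phase_ms, q_uc, d, k)


def shannon_chart(
    amplitudes_ua: Sequence[float], phase_ms: float, area_cm2: float
) -> list[ShannonPoint]:
    """Shannon points for a sweep of amplitudes at fixed phase duration."""
    return [shannon_point(a, phase_ms, area_cm2) for a in amplitudes_ua]


def max_safe_amplitude(
    amplitudes_ua: Sequence[float],
    phase_ms: float,
    area_cm2: float,
    k_limit: float = K_NO_DAMAGE,
) -> float:
    """Largest tested amplitude whose Shannon point satisfies k <= k_limit.

    Raises
    ------
    ValueError
        If no tested amplitude is safe under ``k_limit``.
    """
    if len(amplitudes_ua) == 0:
        raise ValueError("amplitude list is empty")
    safe = [p.amplitude_ua for p in shannon_chart(amplitudes_ua, phase_ms, area_cm2)
            if p.k <= k_limit]
    if not safe:
        raise ValueError(
            f"no safe amplitude: every tested amplitude exceeds k = {k_limit}"
        )
    return max(safe)


#: amplitude sweep used for the corneal-ring safety chart (uA)
DEFAULT_AMPLITUDES_UA = (20.0, 50.0, 100.0, 200.0, 300.0, 400.0)
#: corneal ring electrode geometry (mm)
DEFAULT_RING_INNER_DIAMETER_MM = 3.0
DEFAULT_RING_WIRE_DIAMETER_MM = 0.27
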