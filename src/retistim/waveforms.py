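"""Stimulus waveforms: monophasic / charge-balanced biphasic pulses, trains.

A waveform is a list of piecewise-constant segments ``(duration_ms,
multiplier)`` plus an amplitude scale in uA.  Sign convention: cathodic
current at the stimulating electrode is negative, so a cathodic-first
biphasic pulse has multipliers (-1, +1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = ["Waveform", "monophasic_pulse", "biphasic_pulse", "pulse_train"]

#: pulse-duration range explored in the strength-duration analysis (ms)
DURATION_RANGE_MS = (0.1, 25.0)


def _frac(x) -> Fraction:
    """Exact rational from a float/str duration (via its decimal repr)."""
    return Fraction(str(x))


@dataclass(frozen=True)
class Waveform:
    """Piecewise-constant stimulus.

    ``segments`` are (duration, multiplier) pairs with exact rational
    durations in ms so charge bookkeeping is exact; ``amplitude_ua`` scales
    the dimensionless multipliers to uA.
    """

    segments: tuple[tuple[Fraction, Fraction], ...]
    amplitude_ua: float

    def __post_init__(self):
        if any(d <= 0 for d, _ in self.segments):
            raise ValueError("segment durations must be positive")

    @property
    def duration_ms(self) -> float:
        return float(sum(d for d, _ in self.segments))

    @property
    def net_charge_uc(self) -> float:
        """Net charge in uC (exact rational arithmetic before conversion)."""
        q = sum(d * m for d, m in self.segments)
        return float(q) * self.amplitude_ua * 1e-3

    @property
    def charge_balanced(self) -> bool:
        return sum(d * m for d, m in self.segments) == 0

    def with_amplitude(self, amplitude_ua: float) -> "Waveform":
        return Waveform(self.segments, amplitude_ua)

    def sample(self, dt_ms: float, total_ms: float | None = None) -> np.ndarray:
        """Sample onto a uniform dt grid as current in uA per step.

        Each step value is the segment multiplier at the step's start time;
        when dt divides every segment duration the per-phase charge is
        conserved exactly.
        """
        if dt_ms <= 0:
            raise ValueError("dt must be positive")
        total = self.duration_ms if total_ms is None else total_ms
        n = int(round(total / dt_ms))
        # step i covers [i*dt, (i+1)*dt); classify by midpoint so grids
        # commensurate with the segment edges conserve per-phase charge
        t_mid = (np.arange(n) + 0.5) * dt_ms
        edges = np.cumsum([float(d) for d, _ in self.segments])
        vals = np.array([float(m) for _, m in self.segments] + [0.0])
        idx = np.searchsorted(edges, t_mid, side="right")
        return vals[np.minimum(idx, len(vals) - 1)] * self.amplitude_ua

    def mirrored(self) -> "Waveform":
        """Polarity-inverted copy."""
        return Waveform(tuple((d, -m) for d, m in self.segments), self.amplitude_ua)


def _check_duration(duration_ms: float) -> None:
    if duration_ms <= 0:
        raise ValueError("pulse duration must be positive")
    lo, hi = DURATION_RANGE_MS
    if not lo <= duration_ms <= hi:
        warnings.warn(
            f"pulse duration {duration_ms} ms outside the analyzed "
            f"{lo}-{hi} ms range",
            stacklevel=3,
        )


def monophasic_pulse(amplitude_ua: float, duration_ms: float,
                     polarity: str = "cathodic") -> Waveform:
    """Single-phase rectangular pulse; net charge = amplitude x duration."""
    _check_duration(duration_ms)
    if polarity not in ("cathodic", "anodic"):
        raise ValueError("polarity must be 'cathodic' or 'anodic'")
    m = Fraction(-1 if polarity == "cathodic" else 1)
    return Waveform(((_frac(duration_ms), m),), amplitude_ua)


def biphasic_pulse(amplitude_ua: float, phase_duration_ms: float,
                   interphase_gap_ms: float = 0.0,
                   cathodic_first: bool = True) -> Waveform:
    """Symmetric charge-balanced biphasic pulse (zero net charge by construction)."""
    _check_duration(phase_duration_ms)
    if amplitude_ua <= 0:
        raise ValueError("amplitude must be positive")
    s = Fraction(-1 if cathodic_first else 1)
    d = _frac(phase_duration_ms)
    segs: list[tuple[Fraction, Fraction]] = [(d, s)]
    if interphase_gap_ms > 0:
        segs.append((_frac(interphase_gap_ms), Fraction(0)))
    segs.append((d, -s))
    return Waveform(tuple(segs), amplitude_ua)


def pulse_train(base: Waveform, frequency_hz: float, count: int) -> Waveform:
    """Repeat ``base`` at a fixed frequency, zero-filling between pulses."""
    if count < 1:
        raise ValueError("count must be >= 1")
    if count == 1:
        return base
    period_ms = _frac(1000) / _frac(frequency_hz)
    base_len = sum(d for d, _ in base.segments)
    if period_ms < base_len:
        raise ValueError(
            f"pulses overlap: period {float(period_ms):g} ms < pulse "
            f"duration {float(base_len):g} ms"
        )
    gap = period_ms - base_len
    segs: list[tuple[Fraction, Fraction]] = []
    for i in range(count):
        segs.extend(base.segments)
        if i < count - 1 and gap > 0:
            segs.append((gap, Fraction(0)))
    return Waveform(tuple(segs), base.amplitude_ua)
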