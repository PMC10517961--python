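"""Activation thresholds, strength-duration curves and placement ratios.

The activation threshold is the lowest stimulus amplitude that elicits at
least one action potential.  It is found by doubling an initial seed
amplitude until a spike occurs (bracketing) and then bisecting until the
relative bracket width falls below the search tolerance; the returned
value is the upper bracket end (guaranteed suprathreshold).  Because the
volume conductor is linear, scaling the extracellular field by a factor c
scales every threshold by 1/c.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .engine import CellModel, SimulationConfig, simulate, spikes_in_window
from .waveforms import Waveform, biphasic_pulse, monophasic_pulse

__all__ = [
    "ThresholdSearch",
    "StrengthDurationCurve",
    "ThresholdRatioCurve",
    "find_threshold",
    "strength_duration",
    "threshold_ratio",
    "weiss_fit",
    "DEFAULT_DURATIONS_MS",
]

log = logging.getLogger(__name__)

#: pulse-duration grid for strength-duration analysis (ms)
DEFAULT_DURATIONS_MS = (0.1, 0.3, 1.0, 3.0, 10.0, 25.0)


@dataclass(frozen=True)
class ThresholdSearch:
    """Bracket-and-bisect settings."""

    seed_ua: float = 1000.0
    tolerance: float = 0.02  # relative bracket width
    cap_ua: float = 1e6
    doubling_factor: float = 2.0


class InexcitableError(RuntimeError):
    """No spike up to the amplitude cap."""


class SpontaneousActivityError(RuntimeError):
    """Spiking at zero stimulus amplitude."""


def find_threshold(
    spikes_at: Callable[[float], bool],
    search: ThresholdSearch | None = None,
) -> float:
    """Bisect the lowest spiking amplitude of a monotone stimulus response.

    ``spikes_at(amplitude_ua)`` reports whether the stimulus at that
    amplitude elicits an action potential.  Returns the upper bracket end
    in uA.
    """
    s = search or ThresholdSearch()
    if spikes_at(0.0):
        raise SpontaneousActivityError("cell spikes at zero stimulus amplitude")
    hi = s.seed_ua
    while not spikes_at(hi):
        hi *= s.doubling_factor
        if hi > s.cap_ua:
            raise InexcitableError(
                f"inexcitable under this configuration (no spike up to "
                f"{s.cap_ua:g} uA)"
            )
    lo = 0.0 if hi == s.seed_ua else hi / s.doubling_factor
    while (hi - lo) / hi > s.tolerance:
        mid = 0.5 * (hi + lo)
        if spikes_at(mid):
            hi = mid
        else:
            lo = mid
    return hi


def regenerative_trace(
    model: CellModel,
    ve_unit_v_per_a: np.ndarray,
    waveform: Waveform | None,
    config: SimulationConfig,
    state0=None,
):
    """Passive-referenced detection trace over the sodium-rich region.

    Strong extracellular fields polarize the membrane passively; the
    passive deflection can cross any fixed voltage threshold without a
    regenerative event.  The detection signal is therefore the active
    trace minus the deflection of a passive twin (identical geometry and
    leak, voltage-gated densities zeroed), maximized over the detection
    region.  A spike is a crossing of the detection threshold on this
    corrected trace -- i.e. a depolarization beyond the passive response
    reaching spike height.
    """
    import dataclasses as _dc

    cfg = _dc.replace(config, record_all=True)
    trace = simulate(model, ve_unit_v_per_a, waveform, cfg, state0=state0)
    det = model.cell.detection_indices
    v_act = trace.vm_mv[det]
    if waveform is not None:
        passive = model.passive()
        p0 = passive.equilibrium(cfg)
        tr_p = simulate(passive, ve_unit_v_per_a, waveform, cfg, state0=p0)
        deflection = tr_p.vm_mv[det] - passive.cell.leak_erev_mv
        v_det = (v_act - deflection).max(axis=0)
    else:
        v_det = v_act.max(axis=0)
    from .engine import Trace

    return Trace(t_ms=trace.t_ms, vm_mv=v_det[None, :], stim_ua=trace.stim_ua,
                 detection_row=0, recorded=(int(det[0]),))


def make_spike_test(
    model: CellModel,
    ve_unit_v_per_a: np.ndarray,
    waveform_factory: Callable[[float], Waveform],
    config: SimulationConfig | None = None,
) -> Callable[[float], bool]:
    """Bind cell, unit field and waveform family into an amplitude test."""
    cfg = config or SimulationConfig()
    state0 = model.equilibrium(cfg)

    def spikes_at(amplitude_ua: float) -> bool:
        wave = None if amplitude_ua == 0.0 else waveform_factory(amplitude_ua)
        trace = regenerative_trace(model, ve_unit_v_per_a, wave, cfg, state0)
        return spikes_in_window(trace, cfg) > 0

    return spikes_at


def cell_threshold(
    model: CellModel,
    ve_unit_v_per_a: np.ndarray,
    waveform_factory: Callable[[float], Waveform],
    config: SimulationConfig | None = None,
    search: ThresholdSearch | None = None,
) -> float:
    """Threshold amplitude (uA) for one cell/field/waveform combination."""
    return find_threshold(
        make_spike_test(model, ve_unit_v_per_a, waveform_factory, config), search
    )


@dataclass
class StrengthDurationCurve:
    """Threshold amplitude versus pulse duration."""

    cell: str
    electrode_config: str
    waveform_kind: str  # 'monophasic' | 'biphasic'
    durations_ms: np.ndarray
    thresholds_ua: np.ndarray
    tolerance: float = 0.02

    def __post_init__(self):
        self.durations_ms = np.asarray(self.durations_ms, float)
        self.thresholds_ua = np.asarray(self.thresholds_ua, float)
        if np.any(np.diff(self.durations_ms) <= 0):
            raise ValueError("durations must be strictly increasing")
        if np.any(self.thresholds_ua <= 0):
            raise ValueError("thresholds must be positive")


@dataclass
class ThresholdRatioCurve:
    """Pointwise TES1/TES2 threshold ratio versus pulse duration."""

    cell: str
    durations_ms: np.ndarray
    ratios: np.ndarray

    def __post_init__(self):
        if np.any(np.asarray(self.ratios) <= 0):
            raise ValueError("ratios must be positive")


def waveform_factory(kind: str, duration_ms: float) -> Callable[[float], Waveform]:
    """Amplitude -> waveform family for one pulse kind and duration."""
    if kind == "monophasic":
        return lambda amp: monophasic_pulse(amp, duration_ms, "cathodic")
    if kind == "biphasic":
        return lambda amp: biphasic_pulse(amp, duration_ms, cathodic_first=True)
    raise ValueError(f"unknown waveform kind {kind!r}")


def strength_duration(
    model: CellModel,
    ve_unit_v_per_a: np.ndarray,
    durations_ms: Sequence[float] = DEFAULT_DURATIONS_MS,
    kind: str = "biphasic",
    electrode_config: str = "",
    config: SimulationConfig | None = None,
    search: ThresholdSearch | None = None,
) -> StrengthDurationCurve:
    """One threshold search per duration (warm-started along the curve).

    Monophasic strength-duration curves are expected to be non-increasing
    in duration; violations beyond the search tolerance raise a warning,
    not an error.
    """
    s = search or ThresholdSearch()
    thresholds = []
    seed = s.seed_ua
    for d in durations_ms:
        s_d = dataclasses.replace(s, seed_ua=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # durations are validated here
            thr = cell_threshold(model, ve_unit_v_per_a,
                                 waveform_factory(kind, d), config, s_d)
        thresholds.append(thr)
        seed = thr  # warm start: thresholds shrink slowly with duration
        log.info("threshold %s %s %g ms -> %.4g uA",
                 model.cell.name, kind, d, thr)
    thresholds = np.asarray(thresholds)
    if kind == "monophasic":
        rise = np.diff(thresholds) / thresholds[:-1]
        if np.any(rise > s.tolerance):
            warnings.warn(
                "monophasic strength-duration curve increases with duration "
                f"beyond tolerance (max rise {rise.max():.1%})",
                stacklevel=2,
            )
    return StrengthDurationCurve(
        cell=model.cell.name,
        electrode_config=electrode_config,
        waveform_kind=kind,
        durations_ms=np.asarray(durations_ms, float),
        thresholds_ua=thresholds,
        tolerance=s.tolerance,
    )


def threshold_ratio(
    curve_tes1: StrengthDurationCurve, curve_tes2: StrengthDurationCurve
) -> ThresholdRatioCurve:
    """Pointwise TES1/TES2 threshold ratio; grids and cells must match."""
    if curve_tes1.cell != curve_tes2.cell:
        raise ValueError("curves belong to different cells")
    if not np.array_equal(curve_tes1.durations_ms, curve_tes2.durations_ms):
        raise ValueError("duration grids do not match")
    return ThresholdRatioCurve(
        cell=curve_tes1.cell,
        durations_ms=curve_tes1.durations_ms,
        ratios=curve_tes1.thresholds_ua / curve_tes2.thresholds_ua,
    )


def weiss_fit(curve: StrengthDurationCurve) -> tuple[float, float, float]:
    """Weiss-law fit I_th(PW) = I_rh (1 + chronaxie / PW).

    Returns (rheobase_ua, chronaxie_ms, r_squared) from nonlinear least
    squares on the thresholds (linear charge regression as the initial
    guess).
    """
    from scipy.optimize import curve_fit

    pw = curve.durations_ms
    q = curve.thresholds_ua * pw
    slope, intercept = np.polyfit(pw, q, 1)
    p0 = (max(slope, 1e-9), max(intercept / max(slope, 1e-9), 1e-3))
    (rheobase, chronaxie), _ = curve_fit(
        lambda t, irh, c: irh * (1.0 + c / t), pw, curve.thresholds_ua, p0=p0,
        maxfev=10_000,
    )
    pred = rheobase * (1.0 + chronaxie / pw)
    ss_res = np.sum((curve.thresholds_ua - pred) ** 2)
    ss_tot = np.sum((curve.thresholds_ua - curve.thresholds_ua.mean()) ** 2)
    return float(rheobase), float(chronaxie), float(1.0 - ss_res / ss_tot)
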