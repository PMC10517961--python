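"""Cable integration, resting stability, spike detection."""

import dataclasses
import math

import numpy as np
import pytest

from retistim.cells import Cell, CompartmentChain, assign_channels, bc_channel_table
from retistim.engine import (
    CellModel,
    MembraneState,
    SimulationConfig,
    Trace,
    detect_spikes,
    simulate,
)
from retistim.kinetics import bc_kinetics
from retistim.morphology import Morphology, Section
from retistim.waveforms import biphasic_pulse


def single_compartment(g_leak=0.033, e_leak=-60.0):
    """One passive cylinder compartment with the printed leak values."""
    from retistim.cells import compartmentalize

    morph = Morphology([Section("axon", (0, 0, 0), (0, 0, 20.0), 10.0, 10.0, -1)])
    chain = compartmentalize(morph, 100.0, 1.0, 100.0)
    table = bc_channel_table()
    cell = assign_channels(chain, table, "axon", name="passive1")
    cell.gbar_ms_cm2[:] = 0.0
    cell.leak_ms_cm2[:] = g_leak
    cell = dataclasses.replace(cell, leak_erev_mv=e_leak)
    return CellModel(cell, bc_kinetics())


class TestPassiveRC:
    @pytest.mark.parametrize(
        "g_leak,tau_expect", [(0.033, 1.0 / 0.033), (0.05, 20.0)]
    )
    def test_step_response_matches_rc_closed_form(self, g_leak, tau_expect):
        """A current step into a passive compartment follows
        V(t) = V_inf + (V0 - V_inf) exp(-t/tau) with tau = Cm/g_leak
        (30.3 ms for the bipolar leak, 20 ms for the RGC leak) within 0.5%.
        """
        model = single_compartment(g_leak=g_leak)
        area = model.cell.chain.area_cm2[0]
        i_amp = 2e-5  # 20 pA step
        cfg = SimulationConfig(dt_ms=0.005, settle_ms=0, pre_ms=0,
                               post_ms=5 * tau_expect)
        tr = simulate(model, 0.0, None, cfg,
                      state0=model.init_state(-60.0),
                      i_inj_ua=np.array([i_amp]))
        v_inf = -60.0 + i_amp / (g_leak * area)
        expect = v_inf + (-60.0 - v_inf) * np.exp(-tr.t_ms / tau_expect)
        rel = np.abs(tr.vm_mv[0] - expect) / np.abs(v_inf - (-60.0))
        assert rel.max() < 0.005

    def test_relaxation_time_constant(self):
        """Displace a passive compartment and check the measured e-folding
        time equals Cm/g_l = 30.3 ms within 0.5%."""
        model = single_compartment()
        cfg = SimulationConfig(dt_ms=0.005, settle_ms=0, pre_ms=0, post_ms=100)
        tr = simulate(model, 0.0, None, cfg, state0=model.init_state(-50.0))
        v = tr.vm_mv[0]
        # time to decay to 1/e of the initial 10 mV displacement
        target = -60.0 + 10.0 / math.e
        i = np.argmax(v < target)
        tau = tr.t_ms[i]
        assert tau == pytest.approx(1.0 / 0.033, rel=0.005)


class TestRestingState:
    @pytest.mark.parametrize("model_name", ["bc_model", "rgc_model"])
    def test_settled_cells_are_quiescent(self, model_name, request, sim_config):
        """After the settle period, zero stimulus leaves every compartment
        with |dVm/dt| < 1e-4 mV/ms and no spontaneous spikes."""
        model = request.getfixturevalue(model_name)
        cfg = dataclasses.replace(sim_config, pre_ms=0.0, post_ms=20.0,
                                  record_all=True)
        tr = simulate(model, 0.0, None, cfg)
        dvdt = np.abs(np.diff(tr.vm_mv, axis=1)) / cfg.dt_ms
        assert dvdt.max() < 1e-4
        assert len(detect_spikes(tr, cfg)) == 0

    @pytest.mark.parametrize("model_name", ["bc_model", "rgc_model"])
    def test_relaxation_toward_rest_is_monotone(self, model_name, request):
        """With stimuli off, the whole-cell deviation from rest decays
        (no spontaneous regenerative activity from a displaced start)."""
        model = request.getfixturevalue(model_name)
        cfg = SimulationConfig(settle_ms=0, pre_ms=0, post_ms=300,
                               record_all=True)
        tr = simulate(model, 0.0, None, cfg,
                      state0=model.init_state(-65.0))
        rest = tr.vm_mv[:, -1:]
        dev = np.abs(tr.vm_mv - rest).max(axis=0)
        # after the fast gate transients (first 100 ms), the envelope decays
        late = dev[10000::2000]
        assert np.all(np.diff(late) < 1e-3)
        assert dev[-1] < 0.5
        assert len(detect_spikes(tr, cfg)) == 0


class TestExtracellularCoupling:
    def test_uniform_field_leaves_vm_unchanged(self, bc_model, sim_config):
        """Only potential differences drive the cable: a spatially uniform
        extracellular potential has no effect."""
        cfg = dataclasses.replace(sim_config, record_all=True)
        wave = biphasic_pulse(1e5, 5.0)
        tr_unif = simulate(bc_model, 1234.5, wave, cfg)
        tr_quiet = simulate(bc_model, 0.0, None, cfg,
                            duration_ms=float(tr_unif.t_ms[-1]))
        assert np.allclose(tr_unif.vm_mv, tr_quiet.vm_mv, atol=1e-8)

    def test_polarity_and_field_inversion_cancel(self, bc_model, unit_fields,
                                                 sim_config):
        ve = unit_fields["bc", "TES2"]
        cfg = dataclasses.replace(sim_config, record_all=True)
        w = biphasic_pulse(5e4, 1.0, cathodic_first=True)
        tr1 = simulate(bc_model, ve, w, cfg)
        tr2 = simulate(bc_model, -ve, w.mirrored(), cfg)
        assert np.allclose(tr1.vm_mv, tr2.vm_mv, atol=1e-9)

    def test_divergence_reported_with_timestep(self, bc_model):
        cfg = SimulationConfig(settle_ms=0, pre_ms=0, post_ms=1.0)
        bad = np.zeros(bc_model.cell.n)
        bad[0] = np.inf
        with pytest.raises(FloatingPointError, match="step"):
            simulate(bc_model, 0.0, None, cfg, i_inj_ua=bad)


def make_trace(t, v, thr_cfg=None):
    return Trace(t_ms=np.asarray(t, float), vm_mv=np.asarray(v, float)[None, :],
                 stim_ua=np.zeros(len(t)))


class TestSpikeDetection:
    CFG = SimulationConfig(detect_threshold_mv=0.0, refractory_ms=1.0)

    def test_flat_trace_no_spikes(self):
        t = np.arange(100) * 0.1
        tr = make_trace(t, np.full(100, -65.0))
        assert len(detect_spikes(tr, self.CFG)) == 0

    def test_single_crossing_interpolated_time(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        v = np.array([-10.0, -2.0, 6.0, -20.0])
        times = detect_spikes(make_trace(t, v), self.CFG)
        assert len(times) == 1
        assert times[0] == pytest.approx(1.25)  # linear interpolation

    def test_double_crossing_within_refractory_counts_once(self):
        t = np.arange(8) * 0.2
        v = np.array([-10.0, 5.0, -10.0, 5.0, -10.0, -10.0, -10.0, -10.0])
        assert len(detect_spikes(make_trace(t, v), self.CFG)) == 1

    def test_crossings_beyond_refractory_count_separately(self):
        t = np.arange(0, 6.0, 0.5)
        v = np.full_like(t, -10.0)
        v[2] = 5.0
        v[8] = 5.0
        assert len(detect_spikes(make_trace(t, v), self.CFG)) == 2

    def test_threshold_bounds_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(detect_threshold_mv=50.0)


class TestTraceContract:
    def test_trace_rejects_nonfinite(self):
        with pytest.raises(FloatingPointError):
            make_trace([0.0, 0.1], [0.0, np.nan])

    def test_simulate_trace_length(self, bc_model):
        cfg = SimulationConfig(settle_ms=0, pre_ms=1.0, post_ms=2.0)
        w = biphasic_pulse(10.0, 1.0)
        tr = simulate(bc_model, 0.0, w, cfg)
        assert len(tr.t_ms) == int(round((1.0 + 2.0 + 2.0) / cfg.dt_ms))
        assert tr.stim_ua.min() == -10.0 and tr.stim_ua.max() == 10.0
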