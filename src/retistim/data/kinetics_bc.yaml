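# Spiking bipolar-cell channel kinetics: HH-style Na and fast K with
# activation shifted +20 mV relative to the ganglion-cell rates (bipolar
# sodium channels activate at more depolarized potentials, and the shift
# keeps the high-density axon electrically silent at rest), a slow
# delayed-rectifier K, L- and T-type Ca activation curves and an HCN
# (h-type) activation curve from published retinal bipolar models.
# Rates per ms, potentials mV.
name: db4_bc
channels:
  g_Na:
    ion: na
    erev_mv: 35.0
    gates:
      - exponent: 3
        alpha: {form: exp_linear, k: 0.6, v0: -15.0, s: 10.0}
        beta: {form: exponential, k: 20.0, v0: -40.0, s: -18.0}
      - exponent: 1
        alpha: {form: exponential, k: 0.4, v0: -50.0, s: -20.0}
        beta: {form: sigmoid, k: 6.0, v0: -20.0, s: 10.0}
  g_Kfast:
    ion: k
    erev_mv: -75.0
    gates:
      - exponent: 4
        alpha: {form: exp_linear, k: 0.02, v0: -20.0, s: 10.0}
        beta: {form: exponential, k: 0.4, v0: -30.0, s: -80.0}
  g_Kslow:
    ion: k
    erev_mv: -75.0
    gates:
      - exponent: 1
        inf: {form: sigmoid, k: 1.0, v0: -50.0, s: 9.0}
        tau: {form: constant, k: 20.0}
  g_caL:
    ion: ca
    erev_mv: nernst_ca
    gates:
      - exponent: 2
        inf: {form: sigmoid, k: 1.0, v0: -25.0, s: 6.0}
        tau: {form: constant, k: 2.0}
  # low-threshold T-type: activates just above rest with slow kinetics, so
  # long pulses recruit it; deinactivation during the cathodic phase powers
  # the rebound response to the second phase of long biphasic pulses
  g_caT:
    ion: ca
    erev_mv: nernst_ca
    gates:
      - exponent: 2
        inf: {form: sigmoid, k: 1.0, v0: -60.0, s: 6.0}
        tau: {form: constant, k: 15.0}
      - exponent: 1
        inf: {form: sigmoid, k: 1.0, v0: -81.0, s: -5.0}
        tau: {form: constant, k: 30.0}
  g_HCN:
    ion: h
    erev_mv: -30.0
    gates:
      - exponent: 1
        inf: {form: sigmoid, k: 1.0, v0: -90.0, s: -5.5}
        tau: {form: constant, k: 200.0}
ca_pool:
  k_mm_cm2_per_ua_ms: 1.55e-5
  tau_ms: 20.0
  rest_mm: 1.0e-4
  floor_mm: 1.0e-6
  ca_out_mm: 1.8
  rt_over_2f_mv: 13.35
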