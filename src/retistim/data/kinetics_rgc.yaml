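# A2-RGC channel kinetics: five-conductance retinal ganglion cell
# formulation of the Fohlmeister-Miller lineage (Na m3h, K n4, A-type K
# a3hA, Ca c3 feeding a single calcium pool, Ca-dependent K slaved to the
# pool), plus h-current and low-threshold T-type Ca formulations from the
# retinal modeling literature.  Rates per ms, potentials mV.
name: a2_rgc
channels:
  g_Na:
    ion: na
    erev_mv: 35.0
    gates:
      - exponent: 3
        alpha: {form: exp_linear, k: 0.6, v0: -30.0, s: 10.0}
        beta: {form: exponential, k: 20.0, v0: -55.0, s: -18.0}
      - exponent: 1
        alpha: {form: exponential, k: 0.4, v0: -50.0, s: -20.0}
        beta: {form: sigmoid, k: 6.0, v0: -20.0, s: 10.0}
  g_K:
    ion: k
    erev_mv: -75.0
    gates:
      - exponent: 4
        alpha: {form: exp_linear, k: 0.02, v0: -40.0, s: 10.0}
        beta: {form: exponential, k: 0.4, v0: -50.0, s: -80.0}
  g_K_A:
    ion: k
    erev_mv: -75.0
    gates:
      - exponent: 3
        alpha: {form: exp_linear, k: 0.006, v0: -90.0, s: 10.0}
        beta: {form: exponential, k: 0.1, v0: -30.0, s: -10.0}
      - exponent: 1
        alpha: {form: exponential, k: 0.04, v0: -70.0, s: -20.0}
        beta: {form: sigmoid, k: 0.6, v0: -40.0, s: 10.0}
  g_K_Ca:
    ion: k
    erev_mv: -75.0
    ca_gate: {kd_mm: 1.0e-3, power: 2}
  g_Ca:
    ion: ca
    erev_mv: nernst_ca
    gates:
      - exponent: 3
        alpha: {form: exp_linear, k: 0.3, v0: -13.0, s: 10.0}
        beta: {form: exponential, k: 10.0, v0: -38.0, s: -18.0}
  g_h:
    ion: h
    erev_mv: -30.0
    gates:
      - exponent: 1
        inf: {form: sigmoid, k: 1.0, v0: -80.0, s: -8.0}
        tau: {form: constant, k: 300.0}
  g_T:
    ion: ca
    erev_mv: nernst_ca
    gates:
      - exponent: 2
        inf: {form: sigmoid, k: 1.0, v0: -50.0, s: 7.4}
        tau: {form: constant, k: 5.0}
      - exponent: 1
        inf: {form: sigmoid, k: 1.0, v0: -78.0, s: -5.0}
        tau: {form: constant, k: 40.0}
ca_pool:
  k_mm_cm2_per_ua_ms: 1.55e-5
  tau_ms: 20.0
  rest_mm: 1.0e-4
  floor_mm: 1.0e-6
  ca_out_mm: 1.8
  rt_over_2f_mv: 13.35
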