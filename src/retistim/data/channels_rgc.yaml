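# Maximum ionic conductance densities of the A2 retinal ganglion cell model.
# Units: S/cm^2 (converted to mS/cm^2 on load).  The A-type and
# calcium-dependent potassium densities are slaved to the delayed
# rectifier: g_K,A = 3*g_K everywhere, g_K,Ca = 0.004*g_K in soma and
# dendrites.  The leak is uniform: 0.05 mS/cm^2, reversal -60 mV.
name: a2_rgc
units: S/cm2
regions: [soma, dendrite, AH, SOCB, NS, DA]
channels:
  g_Na:
    soma: 0.35
    dendrite: 0.1
    AH: 0.8
    SOCB: 2.4
    NS: 0.9
    DA: 0.8
  g_K:
    soma: 0.12
    dendrite: 0.05
    AH: 0.6
    SOCB: 0.8
    NS: 0.6
    DA: 0.6
  g_K_A:
    soma: 3 * g_K
    dendrite: 3 * g_K
    AH: 3 * g_K
    SOCB: 3 * g_K
    NS: 3 * g_K
    DA: 3 * g_K
  g_K_Ca:
    soma: 0.004 * g_K
    dendrite: 0.004 * g_K
  g_Ca:
    soma: 0.137
    dendrite: 0.05
  g_h:
    soma: 0
    dendrite: 0
  g_T:
    soma: 0.004
    dendrite: 0
leak:
  density_ms_cm2: 0.05
  erev_mv: -60.0
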