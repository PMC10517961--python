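# Maximum ionic conductance densities of the DB4 spiking bipolar cell model.
# Units: mS/cm^2.  Absent entries are zero.  The leak (g_l) is uniform.
name: db4_bc
units: mS/cm2
regions: [soma, dendrite, axon, presynaptic_terminal, terminal]
channels:
  g_Na:
    axon: 1000
  g_Kslow:
    soma: 0.6
    dendrite: 2.4
  g_Kfast:
    axon: 2
  g_caL:
    presynaptic_terminal: 1
  g_caT:
    soma: 1
    dendrite: 1
  g_HCN:
    presynaptic_terminal: 3.25
leak:
  density_ms_cm2: 0.033
  erev_mv: -60.0
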