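# TES1 vs TES2 threshold-ratio experiment: strength-duration curves for
# the spiking bipolar cell and the A2 RGC under both electrode placements,
# biphasic cathodic-first pulses over the default duration grid.
grid:
  domain_mm: 20.0
  spacing_mm: 0.2
electrodes:
  configs: [TES1, TES2]
  ring_diameter_mm: 3.0
cells: [bc, rgc]
waveforms:
  kinds: [biphasic]
  durations_ms: [0.1, 0.3, 1.0, 3.0, 10.0, 25.0]
search:
  tolerance: 0.02
  seed_ua: 1000.0
  cap_ua: 1.0e+8
simulation:
  dt_ms: 0.01
  settle_ms: 400.0
  post_ms: 10.0
stages: [field, thresholds]
output:
  directory: retistim_out/ratio
seed: 0
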