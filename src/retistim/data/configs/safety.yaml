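# Shannon safety chart for the corneal platinum ring electrode
# (3 mm inner diameter, 270 um wire) with 10 ms phases over the
# 20-400 uA amplitude range.
safety:
  amplitudes_ua: [20, 50, 100, 200, 300, 400]
  phase_ms: 10.0
  ring_inner_diameter_mm: 3.0
  wire_diameter_mm: 0.27
  contact_fraction: 1.0
  k_limit: 1.5
stages: [safety]
output:
  directory: retistim_out/safety
seed: 0
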