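# Larval light/dark assay: 24-well plate, 45-min recording at 25 fps.
# 15 min light (baseline + L0) then three 5-min dark / 5-min light cycles.
paradigm: light_dark
stage: larva
fps: 25
arena:
  shape: circle
  diameter_mm: 16.0    # single well of a 24-well plate
  id: well24
schedule:
  baseline_s: 600
  l0_s: 300
  cycle_epoch_s: 300
  n_cycles: 3
  lux_light: 100
duration_s: 2700
bin_s: 30
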