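# Adult open-field assay: 30 x 30 cm opaque tank, 30-min recording.
# Thigmotaxis uses the equal-area periphery/center split.
paradigm: open_field
stage: adult
fps: 25
arena:
  shape: rectangle
  width_mm: 300.0
  height_mm: 300.0
  id: open_field_tank
partition: equal_area_split
duration_s: 1800
bin_s: 30
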