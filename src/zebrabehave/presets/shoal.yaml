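# Shoaling: six same-genotype adults in the novel tank, 30-min recording.
paradigm: shoal
stage: adult
fps: 25
arena:
  shape: rectangle
  width_mm: 240.0      # novel-tank footprint
  height_mm: 150.0
  id: novel_tank
n_fish: 6
duration_s: 1800
bin_s: 30
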