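# Adult social preference: test half of a 21 x 11 cm mating tank, divider
# along the +x edge with 6 conspecifics beyond it; 30-min recording.
paradigm: social_adult
stage: adult
fps: 25
arena:
  shape: rectangle
  width_mm: 105.0      # half of the 210 mm tank length
  height_mm: 110.0
  id: mating_tank_half
partition: adult_sectors
conspecific_side: "+x"
duration_s: 1800
bin_s: 30
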