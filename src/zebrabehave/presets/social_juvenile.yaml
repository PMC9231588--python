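# Juvenile social preference: single well of a 12-well plate, stimulus well
# above (+y). 10-min baseline (partitions opaque) then 10-min test.
# Conspecific/empty sectors are the quarter-zone bands cut at +/- d/4.
paradigm: social_juvenile
stage: adult
fps: 25
arena:
  shape: circle
  diameter_mm: 22.1    # single well of a 12-well plate
  id: well12
partition: juvenile_sectors
conspecific_side: "+y"
baseline_s: 600
test_s: 600
bin_s: 30
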