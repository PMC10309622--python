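name: human
reference: false
column:
  # Short olfactory cleft path with a wide channel; no parallel-coil feature.
  length: 0.047
  channel_width: 1.0e-3
  mucus_thickness: 3.0e-5
  volume_ratio: 1.0
odorant:
  name: calibration-odorant
  beta: 1.0
  Da: 6.0e-6
  Dm: 1.0e-9
k_prime: 1.0
# Olfactory-cleft velocity well above the optimum: the actual plate number
# (~2) falls far short of the peak (~17).
operating_velocity: 0.15
notes: >
  Back-derived calibration (not measured): the human olfactory region lacks
  the parallel-coil feature, so its operating velocity is an order of
  magnitude above the plate-number optimum.
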