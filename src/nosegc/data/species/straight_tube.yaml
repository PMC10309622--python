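name: straight_tube
reference: false
column:
  # Straight-line distance between olfactory inlet and outlet.
  length: 0.0264
  # Channel width = tube diameter, derived from the dorsal-medial stream
  # inlet area rule: A = dm_flow / dm_velocity, D = sqrt(4A/pi).
  dm_flow: 4.4e-6      # 20% of the 22 ml/s restful flow
  dm_velocity: 0.3
  mucus_thickness: 3.0e-5
  volume_ratio: 1.0
odorant:
  name: calibration-odorant
  beta: 1.0
  Da: 6.0e-6
  Dm: 1.0e-9
k_prime: 1.0
# The dorsal-medial stream velocity persists down the tube.
operating_velocity: 0.3
notes: >
  Amphibian-like single straight olfactory channel occupying the same skull
  space: the dorsal-medial stream extends at constant diameter to the
  pharynx, so it operates at the full ~0.3 m/s stream velocity.
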