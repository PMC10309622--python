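name: rat
reference: false
column:
  # Shorter coiled ethmoid path than the cat, with narrower channels.
  length: 0.089
  channel_width: 2.5e-4
  mucus_thickness: 3.0e-5
  volume_ratio: 1.0
odorant:
  name: calibration-odorant
  beta: 1.0
  Da: 6.0e-6
  Dm: 1.0e-9
k_prime: 1.0
# Olfactory-region velocities sit near the plate-number optimum (~0.009 m/s).
operating_velocity: [0.006, 0.02]
notes: >
  Back-derived calibration (not measured): a parallel-coil olfactory region
  like the cat's but smaller, operating near its optimal velocity.
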