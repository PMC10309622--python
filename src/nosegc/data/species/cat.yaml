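name: cat
reference: true
column:
  # Averaged olfactory path length: posterior dorsal-medial channel (0.030 m)
  # plus coiled ethmoid channel (0.151 m), as sampled by mean_path_length on
  # the default cat-like network.
  length: 0.181
  # Averaged coil channel width (slit narrow dimension).
  channel_width: 5.0e-4
  mucus_thickness: 3.0e-5
  volume_ratio: 1.0
odorant:
  name: calibration-odorant
  beta: 1.0
  Da: 6.0e-6
  Dm: 1.0e-9
k_prime: 1.0
# Computed coil airflow velocity range at restful breathing (22 ml/s).
operating_velocity: [0.01, 0.11]
notes: >
  Back-derived calibration: the column geometry and transport coefficients
  are chosen to satisfy the documented physical constraints (30 um mucus
  film, dorsal-medial stream at ~0.3 m/s carrying 15-20% of 22 ml/s, coil
  velocities 0.01-0.11 m/s); they are not measured values.
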