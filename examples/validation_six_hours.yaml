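# Six-hour scenario with a 45 uM exterior bath — the configuration used
# to compare simulated penetration profiles against mouse IP-dosing data.
seed: 7
coupling_mode: wall_coupled

network:
  kind: synthetic
  n_inlets: 5
  n_outlets: 6
  channel_width_mm: 0.05

drug:
  C_surface: {value: 45, units: uM}

time:
  duration: 21600
  dt: 1.0
  checkpoints: [5400, 10800, 16200, 21600]

output: out/validation_six_hours
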