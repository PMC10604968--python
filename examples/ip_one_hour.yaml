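# One-hour intraperitoneal Doxorubicin scenario on the synthetic
# five-inlet / six-outlet vessel tree (all values are the model defaults,
# spelled out with their units for reference).
seed: 7
coupling_mode: wall_coupled

network:
  kind: synthetic
  n_inlets: 5
  n_outlets: 6
  channel_width_mm: 0.05

geometry:
  axis_lengths_mm: [4.85, 3.51]   # printed full axis lengths

tissue:
  K: 3.0e-14                       # m^2/(Pa s)
  L_p: 2.1e-11                     # m/(Pa s)
  S_over_V: 2.0e+4                 # 1/m
  P_B: 2100.0                      # Pa
  pi_B: 2700.0                     # Pa
  pi_i: 2000.0                     # Pa
  sigma_s: 0.9

bcs:
  inlet_pressure: {value: 25, units: mmHg}
  outlet_pressure: {value: 10, units: mmHg}
  surface_pressure: 0.0

drug:
  D_F: {value: 3.40e-6, units: cm^2/s}
  P_wall: {value: 3.00e-4, units: cm/s}
  K_ON: 0.15                       # m^3/(mol s)  (1.5e2 per molar-second)
  K_OFF: 8.0e-3                    # 1/s
  K_INT: 5.0e-5                    # 1/s
  C_rec: {value: 1.0e-5, units: M}
  phi: 0.3
  sigma_f: 0.9
  C_P: 0.0                         # IP dosing: no drug in plasma
  C_surface: 0.8                   # mol/m^3

mesh:
  h_interior: 0.08                 # mm
  n_bl_layers: 21
  bl_growth: 1.2

time:
  duration: 3600
  dt: 1.0
  checkpoints: [900, 1800, 2700, 3600]

metrics:
  omega: 0.6603                    # m^3/mol
  axes_deg: [0, 45, 90, 135]

output: out/ip_one_hour
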