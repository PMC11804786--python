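# Desk-scale demo: generate a synthetic branch, simulate the ambient flow,
# derive internal-flow statistics and project two acidification scenarios.
seed: 7
stages: [generate, simulate, analyze, dissolve]

geometry:
  params:
    shape: [48, 48, 72]
    cylinder_radius: 11.0
    cylinder_height: 56
    channel_radius: 3.0
    n_corallites: 8
    corallite_radius: 2.0
    bump_amplitude: 2.0
    apical_radius: 4.0
    spacing: 0.000545   # 22-voxel diameter -> 1.2 cm branch

flow:
  u_inlet: 0.0009       # m/s; Re = 10.8 for a 1.2 cm branch
  nu: 1.0e-6
  width: 0.012
  max_steps: 4000
  ramp_steps: 300
  check_every: 100
  tol: 5.0e-5

analysis:
  n_particles: 200
  seed_radius: 5.0
  residence_region: channel_top
  confidence: 0.95
  max_steps: 8000

dissolution:
  pipe: {R_O: 0.006, R_I: 0.001, H: 0.04, n0: 0.5}
  scenarios:
    - {kind: inside-acid, pH: 8.10, t: 3.1557e+7, label: "2023"}
    - {kind: inside-acid, pH: 7.87, t: 3.1557e+7, label: "2100"}
    - {kind: outside-acid, pH: 7.87, t: 3.1557e+7, Q: 1.0e-10, label: "2100-influx"}
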