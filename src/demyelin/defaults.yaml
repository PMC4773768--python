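# Default model configuration (surrogate amphibian-node-scale values).
# Units: conductances mS per node, potentials mV, lengths mm,
# resistances kOhm, capacitance pF, durations ms.
channels:
  g_na: 6.0e-4
  g_kf: 1.2e-4
  g_ks: 6.0e-5
  g_leak: 2.0e-5
  e_na: 50.0
  e_kf: -90.0
  e_ks: -90.0
  e_leak: -70.0
  vth_na: -50.0
  vth_kf: -30.0
  vth_ks: -30.0
  vth_leak: -70.0   # at the resting potential: leak branch statically open
geometry:
  internodal_length: 2.0
  n_nodes: 21
  axial_resistance: 15000.0   # 15 MOhm per internode
  nodal_capacitance: 11.0
  baseline_myelin_thickness: 1.79
layout:
  n_neighbors: 6
  alignment: 1.0
  ephaptic_coupling: 0.05
  external_resistance: 5000.0
state:
  gamma: 0.0
  block_fraction: 0.0
gating:
  open_duration_na: 0.3
  open_duration_kf: 1.0
  open_duration_ks: 2.0
  open_duration_leak: .inf
  refractory: 3.0
resting_potential: -70.0
capacitance_gamma_exponent: 1.0
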