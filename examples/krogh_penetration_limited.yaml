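# Penetration-limited example: phi^2 = k_e*[Ag]/((PS/V)*[Ab]) = 100.
# Target-mediated consumption overwhelms delivery; only a perivascular rim
# of receptors is occupied (binding-site barrier).
physiology:
  capillary_radius_m: 8.0e-6
  krogh_radius_m: 75.0e-6
  void_fraction: 0.24
  diffusivity_m2_s: 1.0e-11
  ps_over_v_per_s: 6.0e-6
  cell_density_per_l: 3.0e11
internalization_rate_per_s: 5.0e-5
antigen_total_m: 1.2e-6
plasma_forcing_m: 1.0e-7
binding_on_rate_per_m_s: 1.0e5
binding_off_rate_per_s: 1.0e-4
radial_grid_points: 64
time_horizon_s: 2.0e6
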