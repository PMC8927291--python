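# Built-in agent registry: package-insert doses, plasma exposure, and target
# parameters for FDA-approved solid-tumor ADCs (plus mirvetuximab soravtansine,
# with Enhertu entered twice for IHC 3+ and IHC 2+ HER2 expression) and
# PD-1/PD-L1 checkpoint inhibitors.
#
# Units in this file follow clinical convention: half-lives in hours,
# concentrations in micromolar, doses in mg/kg (per_kg) or mg (flat).
# Everything is converted to SI on load.
#
# Notes:
# - PD-1 rows (nivolumab, pembrolizumab, cemiplimab, dostarlimab) share a
#   36 h internalization half-life and 5,600 receptors/cell; PD-L1 rows
#   (atezolizumab, avelumab) share 35 h and 134,000 receptors/cell.
#   Dostarlimab is pharmacologically an anti-PD-1 antibody and is classed as
#   such here.
# - PS/V = 6e-6 /s for all agents (tumor vascular delivery rate constant).
# - Trodelvy's trough concentration is effectively zero (rapid deconjugation
#   and clearance); it is entered as 0.0 and downstream reports render the
#   trough Thiele modulus as "unbounded".
# - Molecular weights are nominal whole-construct values used only when a
#   C_max must be estimated from dose; the tabulated C_max/C_trough are
#   always preferred.
agents:
  - name: Trodelvy
    agent_class: adc
    target:
      target_name: Trop-2
      receptors_per_cell: 250000
      internalization_half_life_h: 4.06
    exposure:
      dose_amount: 10.0
      dose_basis: per_kg
      schedule_text: "10 mg/kg D1 and D8 of 21-day cycle"
      molecular_weight_g_mol: 160000
      c_max_uM: 1.73
      c_trough_uM: 0.0
    ps_over_v_per_s: 6.0e-6
    provenance:
      - "FDA package insert (sacituzumab govitecan)"
      - "published Trop-2 quantification and internalization kinetics"
  - name: Kadcyla
    agent_class: adc
    target:
      target_name: HER2
      receptors_per_cell: 1000000
      internalization_half_life_h: 7.0
    exposure:
      dose_amount: 3.6
      dose_basis: per_kg
      schedule_text: "3.6 mg/kg Q3W"
      molecular_weight_g_mol: 148000
      c_max_uM: 0.639
      c_trough_uM: 0.0168
    ps_over_v_per_s: 6.0e-6
    provenance:
      - "FDA package insert (ado-trastuzumab emtansine)"
      - "published HER2 quantification on high-expressing tumor cells"
  - name: Enhertu (IHC3+)
    agent_class: adc
    target:
      target_name: HER2
      receptors_per_cell: 1000000
      internalization_half_life_h: 7.0
    exposure:
      dose_amount: 5.4
      dose_basis: per_kg
      schedule_text: "5.4 mg/kg Q3W"
      molecular_weight_g_mol: 154000
      c_max_uM: 1.01
      c_trough_uM: 0.0787
    ps_over_v_per_s: 6.0e-6
    provenance:
      - "FDA package insert (trastuzumab deruxtecan)"
      - "HER2 IHC 3+ expression level"
  - name: Enhertu (IHC2+)
    agent_class: adc
    target:
      target_name: HER2
      receptors_per_cell: 100000
      internalization_half_life_h: 7.0
    exposure:
      dose_amount: 5.4
      dose_basis: per_kg
      schedule_text: "5.4 mg/kg Q3W"
      molecular_weight_g_mol: 154000
      c_max_uM: 1.01
      c_trough_uM: 0.0682
    ps_over_v_per_s: 6.0e-6
    provenance:
      - "FDA package insert (trastuzumab deruxtecan)"
      - "HER2 IHC 2+ expression level"
  - name: Padcev
    agent_class: adc
    target:
      target_name: Nectin-4
      receptors_per_cell: 115000
      internalization_half_life_h: 18.0
    exposure:
      dose_amount: 1.25
      dose_basis: per_kg
      schedule_text: "1.25 mg/kg D1, D8 and D15 of 28-day cycle"
      molecular_weight_g_mol: 152000
      c_max_uM: 0.284
      c_trough_uM: 0.0682
    ps_over_v_per_s: 6.0e-6
    provenance:
      - "FDA package insert (enfortumab vedotin)"
      - "Nectin-4 quantification on T47D cells; ~18 h internalization half-life"
  - name: Mirvetuximab soravtansine
    agent_class: adc
    target:
      target_name: FR-alpha
      receptors_per_cell: 1000000
      internalization_half_life_h: 32.0
    exposure:
      dose_amount: 6.0
      dose_basis: per_kg
      schedule_text: "6 mg/kg Q3W"
      molecular_weight_g_mol: 148000
      c_max_uM: 1.09
      c_trough_uM: 0.054
    ps_over_v_per_s: 6.0e-6
    provenance:
      - "FDA package insert (mirvetuximab soravtansine)"
      - "folate receptor alpha expression; slow internalization/recycling"
  - name: Tivdak
    agent_class: adc
    target:
      target_name: Tissue factor (TF)
      receptors_per_cell: 112000
      internalization_half_life_h: 3.7
    exposure:
      dose_amount: 2.0
      dose_basis: per_kg
      schedule_text: "2 mg/kg Q3W"
      molecular_weight_g_mol: 153000
      c_max_uM: 0.355
      c_trough_uM: 0.00933
    ps_over_v_per_s: 6.0e-6
    provenance:
      - "FDA package insert (tisotumab vedotin)"
      - "tissue factor quantification; 3.7 h internalization half-life"
  - name: Nivolumab
    agent_class: checkpoint_pd1
    target:
      target_name: PD-1
      receptors_per_cell: 5600
      internalization_half_life_h: 36.0
    exposure:
      dose_amount: 240.0
      dose_basis: flat
      schedule_text: "240 mg Q2W"
      molecular_weight_g_mol: 146000
      c_max_uM: 0.594
      c_trough_uM: 0.39
    ps_over_v_per_s: 6.0e-6
    provenance:
      - "FDA package insert (nivolumab)"
      - "PD-1 quantification on tumor-resident lymphocytes"
  - name: Pembrolizumab
    agent_class: checkpoint_pd1
    target:
      target_name: PD-1
      receptors_per_cell: 5600
      internalization_half_life_h: 36.0
    exposure:
      dose_amount: 200.0
      dose_basis: flat
      schedule_text: "200 mg Q3W"
      molecular_weight_g_mol: 149000
      c_max_uM: 0.495
      c_trough_uM: 0.156
    ps_over_v_per_s: 6.0e-6
    provenance:
      - "FDA package insert (pembrolizumab)"
      - "PD-1 quantification on tumor-resident lymphocytes"
  - name: Cemiplimab
    agent_class: checkpoint_pd1
    target:
      target_name: PD-1
      receptors_per_cell: 5600
      internalization_half_life_h: 36.0
    exposure:
      dose_amount: 350.0
      dose_basis: flat
      schedule_text: "350 mg Q3W"
      molecular_weight_g_mol: 146000
      c_max_uM: 0.866
      c_trough_uM: 0.382
    ps_over_v_per_s: 6.0e-6
    provenance:
      - "FDA package insert (cemiplimab)"
      - "PD-1 quantification on tumor-resident lymphocytes"
  - name: Dostarlimab
    agent_class: checkpoint_pd1
    target:
      target_name: PD-1
      receptors_per_cell: 5600
      internalization_half_life_h: 36.0
    exposure:
      dose_amount: 500.0
      dose_basis: flat
      schedule_text: "500 mg Q3W"
      molecular_weight_g_mol: 144000
      c_max_uM: 1.24
      c_trough_uM: 0.278
    ps_over_v_per_s: 6.0e-6
    provenance:
      - "FDA package insert (dostarlimab)"
      - "anti-PD-1 antibody; PD-1 target parameters"
  - name: Atezolizumab
    agent_class: checkpoint_pdl1
    target:
      target_name: PD-L1
      receptors_per_cell: 134000
      internalization_half_life_h: 35.0
    exposure:
      dose_amount: 1200.0
      dose_basis: flat
      schedule_text: "1200 mg Q3W"
      molecular_weight_g_mol: 145000
      c_max_uM: 2.97
      c_trough_uM: 2.01
    ps_over_v_per_s: 6.0e-6
    provenance:
      - "FDA package insert (atezolizumab)"
      - "PD-L1 quantification (tumor cells, T-cells, macrophages)"
  - name: Avelumab
    agent_class: checkpoint_pdl1
    target:
      target_name: PD-L1
      receptors_per_cell: 134000
      internalization_half_life_h: 35.0
    exposure:
      dose_amount: 800.0
      dose_basis: flat
      schedule_text: "800 mg Q2W"
      molecular_weight_g_mol: 147000
      c_max_uM: 1.98
      c_trough_uM: 0.301
    ps_over_v_per_s: 6.0e-6
    provenance:
      - "FDA package insert (avelumab)"
      - "PD-L1 quantification (tumor cells, T-cells, macrophages)"
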