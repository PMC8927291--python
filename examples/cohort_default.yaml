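# Default synthetic cohort: 200 virtual agents spanning the clinical
# envelope of ADC and checkpoint-inhibitor parameters (extended 3x each way).
n_agents: 200
seed: 1
half_life_range_h: [1.2333333333333334, 108.0]
receptors_range: [1866.6666666666667, 3.0e6]
cmax_range_m: [9.466666666666666e-8, 8.91e-6]
trough_ratio_range: [0.02, 0.7]
physiology_jitter: 1.5
include_low_affinity: false
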