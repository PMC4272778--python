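# Bundled meta-analysis selection-bias simulation: the full
# 4 x 4 x 4 x 4 x 3 = 768-scenario grid.
or_levels: [1.0, 0.75, 0.67, 0.50]
selection_levels: [none, weak, moderate, strong]
p_c_levels: [0.30, 0.20, 0.10, 0.05]
tau2_levels: [0.0, 0.05, 0.10, 0.20]
k_levels: [20, 10, 5]
replications: 1000
n_range: [25, 400]
retention:
  none: 1.0
  weak: 0.75
  moderate: 0.5
  strong: 0.25
alpha_select: 0.05
conf_level: 0.95
seed: 20141212
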