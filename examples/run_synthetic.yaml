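# Full pipeline on synthetic study-scale data (20 nodes, 209 participants).
output_dir: scratch/example_run
seed: 7
synthetic:
  n: 209
  seed: 7
synthetic_mode: node
gamma: 0.5
n_lambda: 100
min_ratio: 0.01
correlation: pearson
run_stability: true
stability_grid: [0.1, 0.2, 0.3, 0.4, 0.5]
stability_B: 100
cs_threshold: 0.7
cs_certainty: 0.95
layout_n_init: 10
figures: false
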