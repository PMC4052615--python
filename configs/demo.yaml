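# Demo pipeline configuration. Paths are relative to this file.
out_dir: ../results/demo
dataset_spec: demo_dataset.yaml
seed: 11
features: [ER]
alpha: 0.05
fold: 2.0
n_perm: 200
p_threshold: 1.0e-3
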