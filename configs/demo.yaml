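scenarios: [pr]
n_individuals: 15000
seed: 9
outdir: scratch/pipeline_demo
n_boot: 200
n_sim: 500
or_alt: 1.15
alpha: 0.05
reverse_or_per_5ms: 1.0
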