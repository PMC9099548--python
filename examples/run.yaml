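# Full-workflow example configuration (simulated cohort)
seed: 1
outdir: nodalsig_run
min_genes: 3000
k: 3
n_iterations: 2000
subsample_fraction: 0.6
fdr: 0.05
min_fc: 2.0
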