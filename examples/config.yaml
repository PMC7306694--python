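# Example configuration for `invasion-divscape run --config examples/config.yaml`
seed: 7
out_dir: divscape_demo_run
n_windows: 200          # 5-kb windows per simulated chromosome arm
n_invasive: 2           # bottlenecked populations
n_native: 2             # expanding populations
subsample_individuals: 4
gene_fraction: 0.35
null_iterations: 10
mantel_permutations: 500
rec_bins: 10
n_tpc_populations: 4
tpc_pairs: 12
tpc_steps: 6000
tpc_burn: 2000
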