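# Example pipeline configuration (any subset of PipelineConfig fields).
experiment: "5_4"
n_participants: 10
seed: 7
kappa: 0.8          # signal amplitude per unit attention weight (noise-SD units)
sigma: 1.0          # unit noise SD
n_units: 100
runs: 5
trials_per_run: 16
ga_population: 24
ga_generations: 30
ga_starts: 1
svc_c: 1.0
n_perm: 1000
perm_engine: mixed  # or "ols" for the fast permutation statistic
out_dir: demo_out
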