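# Fully synthetic end-to-end demo: simulate -> filter -> code -> combine ->
# predict -> tree, at desk scale with a reduced MCMC profile (2000/500).
seed: 7
outdir: demo_out
sim:
  n_lines: 40
  n_testers: 4
  n_markers: 300
  n_chromosomes: 10
  n_subpops: 3
  fst: 0.15
  n_qtl: 30
  dominance_ratio: 0.8
  h2_entry: 0.7
  n_envs: 2
  n_reps: 2
  gxe_ratio: 0.2
  residual_het_rate: 0.005
  missing_rate: 0.01
  seed: 0
filter:
  min_dp: 11
  min_gq: 20
  max_maf_excl: 0.05
  max_missing: 0.10
  max_het: 0.05   # simulated inbreds carry ~0.5% residual hets per call
models:
  - method: gblup
  - method: bayes_c
    n_iter: 2000
    burn_in: 500
cv:
  n_folds: 10
  n_repeats: 2
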