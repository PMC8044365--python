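# Prior-sensitivity study grid: normal data, N = 200, the four precision
# priors.  Run desk-scale with:
#   bnpgcm study examples/study.yaml --scale 0.02 --out-dir study_out/
# Full scale (500 replications, 50,000-iteration chains) with --scale 1.
n: 200
n_replications: 500
n_iter: 50000
base_seed: 1
conditions:
  - {alpha_prior: noninformative, label: noninformative}
  - {alpha_prior: weak, label: weak}
  - {alpha_prior: accurate, label: accurate}
  - {alpha_prior: inaccurate, label: inaccurate}
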