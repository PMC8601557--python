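# Demo end-to-end run on a simulated paired study.
#   gutbalance run --config examples/demo_run.yaml --out results/demo
seed: 1
simulate: true
n_patients: 15
n_features: 60
min_prevalence: 0.10
alpha: 0.05
permanova_permutations: 999
sparcc_iterations: 20
sparcc_permutations: 100
C_max: 20
n_folds: 5
n_repeats: 10
parameters: [VO2, Watt, VE]
covariates: [COPD, cancer_type]
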