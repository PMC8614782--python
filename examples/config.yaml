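# Full-pipeline configuration (soacml run --config examples/config.yaml --out out/)
#
# Input is either a compound table:
#   input:
#     compounds: compounds.csv        # columns: id,name,smiles,soac (or k_q)
#     k_ref: 2.3e7                    # reference rate constant, needed for k_q
# or a synthetic ground-truth spec, as below.

input:
  synthetic:
    n_samples: 74
    n_descriptors: 60
    n_fp_bits: 2048
    blocks: [[5, 0.8], [5, 0.8], [5, 0.8], [5, 0.8]]
    fp_density: 0.05
    planted:
      [[desc_0001, 1.0], [desc_0006, 1.0], [desc_0011, 1.0],
       [desc_0021, 1.0], [desc_0031, 1.0]]
    noise_sd: 1.118033988749895
    seed: 0

featurization:
  backend: stub          # stub | toolkit | quantum
  radius: 2
  n_bits: 2048

selection:
  threshold: 0.95        # mandatory correlation cutoff

models:
  algorithms: [xgboost, lightgbm, catboost, random_forest, adaboost, lasso, dnn]
  random_states: [0, 10, 100]
  n_test: null           # null -> 8 when n = 74, else round(n * 8 / 74)
  compute_loocv: true
  hyperparameters:
    random_forest: {n_estimators: 300}
    lasso: {alpha: 0.01}

importance:
  top_k: 7
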