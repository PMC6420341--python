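# Example study configuration for the facebody CLI:
#   facebody replicate --config examples/study.yaml --out results/demo/
schema_version: 1
seed: 7
n_sim_gof: 100           # bootstrap size of the goodness-of-fit screen
prior_scale: 0.707       # Cauchy scale of the directional Bayes factor
robustness_scales: [0.1, 0.2, 0.35, 0.5, 0.707, 1.0, 1.414]
cohort:
  n_observers: 24
  hypothesis: late       # or: early
  face_emotion: disgust
  n_test: 144            # adapted test trials per condition
  n_baseline: 144
  n_adaptation: 24
  n_categorization: 48   # per body context
  delta: {mean: 0.08, sd: 0.02, lo: 0.0, hi: 0.3}   # adaptation shift, morph units
  kappa: {mean: 1.0, sd: 0.0, lo: 0.0, hi: 1.0}     # context-bias strength
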