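# Demo pipeline config: simulate an emulated cohort and run every stage.
#   metaboresponse run --config examples/demo_config.yaml
seed: 7
out_dir: demo_run
alpha: 0.05
simulate:
  n_features: 300
  biofluid: plasma
  frac_affected: 0.333
  rho: 0.9
  effect_sizes: [0.5, 1.0]
  clinical_link:
    PF0000: [weight, 0.25]
pca:
  n_components: 10
  preprocessing: center
lme:
  contrasts: vs_sal
  adjust_for: [weight]
pls:
  factors: [weight]
  B: 200
  folds: 7
  n_components: 2
  q2_threshold: 0.15
  perm_p_threshold: 0.01
chain_match: true
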