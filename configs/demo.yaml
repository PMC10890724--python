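# Demo pipeline configuration: a small synthetic cohort, short chains.
# Full schema: configs/run_config.schema.json (RunConfig in vlsupp.pipeline).
simulation:
  n_per_regimen: {EFV: 200, ATVr: 160, DTG: 80}
  sigma_u: 1.0
weeks: [12, 24, 48, 72, 96]
half_width_days: 28
coef_prior_scale: 2.5
re_sd_prior: 1.0
sampler:
  chains: 2
  iters: 1200
  warmup: 400
selection:
  enabled: true
  candidates: [[regimen, week], [sex, age_group]]
  chains: 2
  iters: 900
  warmup: 300
  check_convergence: false
complete_case: false
figures: true
out_dir: demo_run
seed: 1
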