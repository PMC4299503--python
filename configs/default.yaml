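# Default analysis configuration for `agrimeta analyze`.
# Reproduces the full model set: grand mean, per-covariate subgroup fits,
# landscape slope models with the y > 2 outlier-sensitivity refit, and the
# bias diagnostics block.

subgroup_covariates:
  - functional_group
  - taxon_group
  - crop_type
  - scale

references:
  scale: farm
  functional_group: producers
  taxon_group: arthropods
  crop_type: cereals

landscape_terms:
  # pct_arable enters the slope model as a proportion in [0, 1]
  - {var: pct_arable, kind: continuous, scale: 0.01}
  - {var: n_habitats, kind: continuous}
  - {var: avg_field_size, kind: continuous}

outlier_threshold: 2.0

fit:
  # deterministic quadrature: 201 tau nodes on [0, 10 * sqrt(s2_typical)],
  # phi grid {0, 0.05, ..., 0.95}
  tau_grid_size: 201

seed: 0
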