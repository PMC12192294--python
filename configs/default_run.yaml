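# End-to-end run on the default calibrated synthetic cohort.
# Stages: descriptives -> Cox -> Poisson offsets -> knots -> family
# selection -> geoadditive fits (overall, female, male) -> surfaces.
covariates:
  sex: [female, male]
  residence: [urban, rural]
  alcohol: ["no", "yes"]
strata: sex
families: [exponential, gaussian, matern, spherical, circular, inverse_quadratic]
use_weights: true
project_km: false
reuse_family_for_strata: true
reestimate_tau_per_stratum: true
grid_resolution: 100
outdir: results/run
seed: 11
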