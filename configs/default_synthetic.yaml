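n_clusters: 250
persons_per_cluster: 20
weibull_shape: 7.5
weibull_scale: 8.9
a0: 8.0
interview_age_low: 15.0
interview_age_high: 25.0
integer_year_rounding: true
selection_prob_low: 0.1
selection_prob_high: 1.0
seed: 11
covariates:
- name: sex
  levels:
  - female
  - male
  probs:
  - 0.515
  - 0.485
  betas:
  - 0.0
  - 0.22314355131420976
- name: residence
  levels:
  - urban
  - rural
  probs:
  - 0.44
  - 0.56
  betas:
  - 0.0
  - 0.13976194237515863
- name: alcohol
  levels:
  - 'no'
  - 'yes'
  probs:
  - 0.82
  - 0.18
  betas:
  - 0.0
  - 0.4054651081081644
domain:
  bounds:
  - 0.0
  - 1.0
  - 0.0
  - 1.0
  mask: null
spatial_field:
  bumps:
  - - 0.25
    - 0.75
    - 0.6
    - 0.18
  - - 0.75
    - 0.25
    - -0.6
    - 0.18
  centered: true
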