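# Example simulation config for `kneestudy simulate`.
# Omitted fields take the package defaults (see kneestudy.cohort.CohortConfig).
n_subjects: 100
view: PA
image_size: 192
grade_noise_sd: 0.6
pain_intercept: -0.85
pain_slope: 2.5
transient_flip_prob: 0.15
widespread_fraction: 0.5
widespread_pain_prob: 0.45
demo_params:
  age_mean: 62.3
  age_sd: 8.0
  bmi_mean: 30.7
  bmi_sd: 5.9
  prop_female: 0.6
seed: 1
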