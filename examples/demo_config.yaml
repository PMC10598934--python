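input_csv: null
simulation:
  n_pairs: 371
  traits:
  - light
  - bright
  - brightest
  - cirrus
  causal_paths:
    light->bright: 0.6638597353722749
    bright->light: 0.06421170910553649
    light->brightest: -0.18705989248125862
    bright->brightest: 0.6902778829408632
    cirrus->brightest: 0.1651396986446581
    light->cirrus: 0.11233885819521541
    bright->cirrus: 0.18600368324124844
  familial_loading: {}
  unique_sd:
    light: 0.6121234239957888
    bright: 0.5154147361746506
    brightest: 0.6791441997822163
    cirrus: 0.6974565736958314
  shared_confounders:
  - light: 0.724848321120327
    bright: 0.16066380011203035
    brightest: 0.06931389236171025
    cirrus: 0.1460849275153802
  - bright: 0.2716464062214671
    brightest: 0.10734030829307041
    cirrus: 0.264538436439147
  - brightest: 0.14083351459500776
    cirrus: -0.23936943240651581
  - cirrus: 0.4395706648447211
  age_range:
  - 40.0
  - 70.0
  age_slope:
    light: -0.0165
    bright: -0.034
    brightest: -0.0385
    cirrus: -0.0363
  raw_transform:
    light:
      lam: 0.3333333333333333
      shift: 0.0
      loc: 2.59
      scale: 0.59
    bright:
      lam: 0.3333333333333333
      shift: 0.0
      loc: 2.07
      scale: 0.42
    brightest:
      lam: 0.2
      shift: 0.0
      loc: 1.1
      scale: 0.23
    cirrus:
      lam: 2.0
      shift: -2907.0
      loc: 11.56
      scale: 3.66
  stratifier_range:
  - 10.0
  - 60.0
  seed: 0
transforms:
  light:
    trait: light
    lam: 0.3333333333333333
    shift: 0.0
  bright:
    trait: bright
    lam: 0.3333333333333333
    shift: 0.0
  brightest:
    trait: brightest
    lam: 0.2
    shift: 0.0
  cirrus:
    trait: cirrus
    lam: 2.0
    shift: -2907.0
analyses:
- predictor: light
  outcome: bright
  adjust_for: null
- predictor: bright
  outcome: brightest
  adjust_for: null
- predictor: light
  outcome: brightest
  adjust_for: cirrus
n_bootstrap: 1000
alpha: 0.05
seed: 0
output_dir: falcon_out
standardize_ddof: 1
ci_n_convention: pairs
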