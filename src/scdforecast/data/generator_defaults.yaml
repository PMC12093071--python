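# Default emulation targets for the synthetic cohort generator.
#
# These are NOT real data: they are per-phase marginal frequencies digitized
# from published descriptive tables of a five-phase occupational cohort
# survey (5-year steps, baseline ages 40-60, ~80% women) and serve only as
# targets the simulator calibrates itself to.  Outcome targets for phases 1-3
# are this package's own gentle ramp toward the first tabulated value, since
# the cognitive outcomes were only tabulated at the last two phases.
version: 1
phases: 5
gender_dist: [0.8, 0.2]            # woman, man
education_dist: [0.427, 0.315, 0.258]   # basic, secondary, higher (normalized)
baseline_age_dist: [0.201, 0.212, 0.217, 0.249, 0.121]   # 40,45,50,55,60

persistence:          # probability a lifestyle factor keeps last phase's value
  fruit_veg: 0.8
  smoking: 0.8
  alcohol: 0.8
  ltpa: 0.8
  insomnia: 0.8
  bmi: 0.8

factor_targets:       # per-phase marginals, registry category order
  fruit_veg:          # daily_both, daily_either, nondaily
    - [0.468, 0.293, 0.239]
    - [0.517, 0.283, 0.200]
    - [0.539, 0.273, 0.188]
    - [0.534, 0.250, 0.216]
    - [0.606, 0.240, 0.154]
  smoking:            # never, ex_smoker, current
    - [0.509, 0.243, 0.248]
    - [0.518, 0.293, 0.189]
    - [0.504, 0.341, 0.155]
    - [0.470, 0.390, 0.140]
    - [0.471, 0.428, 0.101]
  alcohol:            # none, moderate, high, very_high
    - [0.070, 0.765, 0.097, 0.067]
    - [0.085, 0.726, 0.102, 0.088]
    - [0.105, 0.735, 0.089, 0.071]
    - [0.142, 0.719, 0.080, 0.059]
    - [0.183, 0.716, 0.057, 0.044]
  ltpa:               # inactive, active
    - [0.252, 0.748]
    - [0.227, 0.773]
    - [0.265, 0.735]
    - [0.242, 0.758]
    - [0.245, 0.755]
  insomnia:           # lt4, 4to14, gt14
    - [0.491, 0.316, 0.193]
    - [0.427, 0.322, 0.250]
    - [0.442, 0.309, 0.249]
    - [0.427, 0.299, 0.274]
    - [0.424, 0.304, 0.272]
  bmi:                # healthy, overweight, obese
    - [0.514, 0.342, 0.144]
    - [0.461, 0.357, 0.182]
    - [0.424, 0.367, 0.209]
    - [0.404, 0.378, 0.219]
    - [0.404, 0.372, 0.224]

outcome_targets:      # per-phase prevalence of the adverse (last) category
  memory:           [0.280, 0.300, 0.310, 0.324, 0.314]
  learning:         [0.420, 0.440, 0.460, 0.477, 0.479]
  concentration:    [0.270, 0.280, 0.290, 0.305, 0.310]
  pain:             [0.446, 0.447, 0.423, 0.437, 0.443]
  hypertension:     [0.229, 0.329, 0.386, 0.515, 0.598]
  high_cholesterol: [0.212, 0.348, 0.432, 0.460, 0.562]
  diabetes:         [0.030, 0.068, 0.114, 0.172, 0.206]
  mental_disorders: [0.185, 0.229, 0.211, 0.206, 0.204]

# additive log-odds effects per category (planted ground truth); intercepts
# are calibrated per phase so marginals still hit the targets above
effects:
  memory: &scd_effects
    age:       [0.0, 0.06, 0.12, 0.18, 0.24, 0.30, 0.36, 0.42, 0.48]
    gender:    [0.0, 0.15]
    ltpa:      [0.0, -0.35]
    alcohol:   [0.30, 0.0, 0.10, 0.40]
    smoking:   [0.0, 0.05, 0.15]
    insomnia:  [0.0, 0.05, 0.15]
    bmi:       [0.0, 0.05, 0.12]
    fruit_veg: [0.0, 0.05, 0.12]
  learning: *scd_effects
  concentration: *scd_effects
  hypertension: &age_effect
    age: [0.0, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80]
  high_cholesterol: *age_effect
  diabetes: *age_effect
  mental_disorders: {}
  pain: {}

missingness:          # per-variable item non-response rate (all phases)
  age: 0.0
  gender: 0.0
  education: 0.01
  fruit_veg: 0.01
  smoking: 0.05
  alcohol: 0.04
  ltpa: 0.01
  insomnia: 0.08
  bmi: 0.02
  hypertension: 0.06
  high_cholesterol: 0.12
  diabetes: 0.15
  mental_disorders: 0.14
  pain: 0.02
  concentration: 0.01
  memory: 0.01
  learning: 0.01

dropout_hazard: 0.06              # per-step probability of leaving the panel
dropout_scd_multiplier: 1.0       # hazard multiplier after a declined-memory phase
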