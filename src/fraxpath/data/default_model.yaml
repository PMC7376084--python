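# Default surrogate hazard configuration (three ethnic groups).
#
# These are NOT FRAX coefficients.  Baseline hazards are Gompertz
# h(a) = alpha * exp(beta * a), chosen so that 10-year hip and MOF
# probabilities for a Singapore-like female cohort fall in the few-percent
# range typical of published East-Asian estimates; relative risks are
# literature-magnitude placeholders.  Edit freely: the case-finding method
# (risk-equivalence thresholds, BMD triage) does not depend on the specific
# engine calibration.
models:
  - ethnicity: chinese
    hazards:
      mof:   {gompertz: [4.3e-06, 0.105]}
      hip:   {gompertz: [4.0e-07, 0.130]}
      death: {gompertz: [7.4e-06, 0.105]}
    log_rr: &default_log_rr
      prior_fracture: 0.5878          # RR 1.8
      parental_hip_fracture: 0.4700   # RR 1.6
      current_smoking: 0.1823         # RR 1.2
      glucocorticoids: 0.4700         # RR 1.6
      rheumatoid_arthritis: 0.3365    # RR 1.4
      secondary_osteoporosis: 0.2624  # RR 1.3
      alcohol_3plus: 0.3365           # RR 1.4
      bmi_per_unit: -0.05             # per kg/m2 above reference 25
    bmd_log_rr_per_sd: 0.4055         # RR 1.5 per SD lower T-score
    bmi_reference: 25.0
    tscore_reference: &default_tref
      mean_at_60: -1.8135
      slope_per_year: -0.045
      sd: 0.80
  - ethnicity: malay
    hazards:
      mof:   {gompertz: [3.7e-06, 0.105]}
      hip:   {gompertz: [3.3e-07, 0.130]}
      death: {gompertz: [8.1e-06, 0.105]}
    log_rr: *default_log_rr
    bmd_log_rr_per_sd: 0.4055
    bmi_reference: 25.0
    tscore_reference: *default_tref
  - ethnicity: indian
    hazards:
      mof:   {gompertz: [3.9e-06, 0.105]}
      hip:   {gompertz: [3.6e-07, 0.130]}
      death: {gompertz: [7.9e-06, 0.105]}
    log_rr: *default_log_rr
    bmd_log_rr_per_sd: 0.4055
    bmi_reference: 25.0
    tscore_reference: *default_tref

# Resident-population ethnic proportions per 5-year age bin (placeholder
# census-like values; each bin sums to 1).
population_weights:
  - {ethnicity: chinese, age_lo: 40, proportion: 0.74}
  - {ethnicity: malay,   age_lo: 40, proportion: 0.14}
  - {ethnicity: indian,  age_lo: 40, proportion: 0.12}
  - {ethnicity: chinese, age_lo: 45, proportion: 0.75}
  - {ethnicity: malay,   age_lo: 45, proportion: 0.14}
  - {ethnicity: indian,  age_lo: 45, proportion: 0.11}
  - {ethnicity: chinese, age_lo: 50, proportion: 0.76}
  - {ethnicity: malay,   age_lo: 50, proportion: 0.13}
  - {ethnicity: indian,  age_lo: 50, proportion: 0.11}
  - {ethnicity: chinese, age_lo: 55, proportion: 0.77}
  - {ethnicity: malay,   age_lo: 55, proportion: 0.13}
  - {ethnicity: indian,  age_lo: 55, proportion: 0.10}
  - {ethnicity: chinese, age_lo: 60, proportion: 0.79}
  - {ethnicity: malay,   age_lo: 60, proportion: 0.12}
  - {ethnicity: indian,  age_lo: 60, proportion: 0.09}
  - {ethnicity: chinese, age_lo: 65, proportion: 0.80}
  - {ethnicity: malay,   age_lo: 65, proportion: 0.11}
  - {ethnicity: indian,  age_lo: 65, proportion: 0.09}
  - {ethnicity: chinese, age_lo: 70, proportion: 0.82}
  - {ethnicity: malay,   age_lo: 70, proportion: 0.10}
  - {ethnicity: indian,  age_lo: 70, proportion: 0.08}
  - {ethnicity: chinese, age_lo: 75, proportion: 0.83}
  - {ethnicity: malay,   age_lo: 75, proportion: 0.09}
  - {ethnicity: indian,  age_lo: 75, proportion: 0.08}
  - {ethnicity: chinese, age_lo: 80, proportion: 0.84}
  - {ethnicity: malay,   age_lo: 80, proportion: 0.09}
  - {ethnicity: indian,  age_lo: 80, proportion: 0.07}
  - {ethnicity: chinese, age_lo: 85, proportion: 0.85}
  - {ethnicity: malay,   age_lo: 85, proportion: 0.08}
  - {ethnicity: indian,  age_lo: 85, proportion: 0.07}

# Mean BMI (kg/m2) by ethnicity and age bin; mild decline with age.
bmi_reference_by_age:
  chinese: {40: 23.6, 45: 23.5, 50: 23.4, 55: 23.3, 60: 23.2, 65: 23.0,
            70: 22.8, 75: 22.5, 80: 22.2, 85: 21.9}
  malay:   {40: 26.2, 45: 26.1, 50: 26.0, 55: 25.9, 60: 25.7, 65: 25.4,
            70: 25.1, 75: 24.7, 80: 24.3, 85: 23.9}
  indian:  {40: 25.4, 45: 25.3, 50: 25.2, 55: 25.1, 60: 24.9, 65: 24.6,
            70: 24.3, 75: 23.9, 80: 23.5, 85: 23.1}

uat_factor: 1.2
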