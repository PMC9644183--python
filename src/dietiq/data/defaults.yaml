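# Default analysis configuration.
#
# Everything here is data, not code: alternative equation sets, band
# definitions or thresholds drop in by overriding these keys.

atwater:            # kcal per gram
  protein: 4.0
  fat: 9.0
  carb: 4.0

# Energy-adequacy rule: intake < energy_threshold * EER is "insufficient".
energy_threshold: 0.85

# Food-composition rows whose stated energy falls outside this fraction of the
# Atwater sum 4P + 9F + 4C are flagged as inconsistent.
fct_consistency_band: [0.70, 1.30]

# Person-day records whose energy differs from the Atwater sum of their
# computed macronutrients by more than this band are flagged.
intake_consistency_band: [0.90, 1.10]

# Reporting age bands (years, lower inclusive, upper exclusive; .inf allowed).
age_bands:
  - {label: "2 to <5 y",  lower: 2.0,  upper: 5.0}
  - {label: "5 to <10 y", lower: 5.0,  upper: 10.0}
  - {label: "10-18 y",    lower: 10.0, upper: 19.0}
  - {label: "19-40 y",    lower: 19.0, upper: 41.0}
  - {label: "41-60 y",    lower: 41.0, upper: 61.0}
  - {label: ">=61 y",     lower: 61.0, upper: .inf}

# Acceptable Macronutrient Distribution Ranges, % of energy intake
# (US Institute of Medicine). Rows partition ages >= 1.
amdr:
  - {age_lower: 1.0,  age_upper: 4.0,  fat: [30.0, 40.0], carb: [45.0, 65.0], protein: [5.0, 20.0]}
  - {age_lower: 4.0,  age_upper: 19.0, fat: [25.0, 35.0], carb: [45.0, 65.0], protein: [10.0, 30.0]}
  - {age_lower: 19.0, age_upper: .inf, fat: [20.0, 35.0], carb: [45.0, 65.0], protein: [10.0, 35.0]}

# FAO/WHO/UNU (2004) weight-based BMR prediction: BMR = slope * weight + intercept
# (kcal/d, weight in kg). Rows partition sex x age >= 0.
bmr_coefficients:
  - {sex: male,   age_lower: 0.0,  age_upper: 3.0,  slope: 59.512, intercept: -30.4}
  - {sex: male,   age_lower: 3.0,  age_upper: 10.0, slope: 22.706, intercept: 504.3}
  - {sex: male,   age_lower: 10.0, age_upper: 18.0, slope: 17.686, intercept: 658.2}
  - {sex: male,   age_lower: 18.0, age_upper: 30.0, slope: 15.057, intercept: 692.2}
  - {sex: male,   age_lower: 30.0, age_upper: 60.0, slope: 11.472, intercept: 873.1}
  - {sex: male,   age_lower: 60.0, age_upper: .inf, slope: 11.711, intercept: 587.7}
  - {sex: female, age_lower: 0.0,  age_upper: 3.0,  slope: 58.317, intercept: -31.1}
  - {sex: female, age_lower: 3.0,  age_upper: 10.0, slope: 20.315, intercept: 485.9}
  - {sex: female, age_lower: 10.0, age_upper: 18.0, slope: 13.384, intercept: 692.6}
  - {sex: female, age_lower: 18.0, age_upper: 30.0, slope: 14.818, intercept: 486.6}
  - {sex: female, age_lower: 30.0, age_upper: 60.0, slope: 8.126,  intercept: 845.6}
  - {sex: female, age_lower: 60.0, age_upper: .inf, slope: 9.082,  intercept: 658.5}

# Physical activity level multipliers on BMR.
pal_levels:
  light: 1.4
  moderate: 1.7
  heavy: 2.0

# Occupation class -> PAL level. The survey occupation codebook is not part of
# this package; this map covers the classes the synthetic generator emits and
# documents the assumption made for non-working members (children, elderly,
# homemakers -> light). Override for real codebooks.
pal_map:
  student: light
  homemaker: light
  none: light
  retired: light
  trader: moderate
  service: moderate
  farmer: heavy
  laborer: heavy

# Dietary-diversity schemes: WHO 7-group for children below the switch age
# (minimum diversity >= 4 groups), MDD-W 10-group otherwise (>= 5 groups).
diversity:
  scheme_switch_age: 10.0
  who7_threshold: 4
  mddw_threshold: 5
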