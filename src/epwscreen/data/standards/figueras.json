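{
 "standard_id": "figueras",
 "family": "customized",
 "efw_formula_id": "hadlock4",
 "parameters": {
  "base_term_weight": 3361.25,
  "reference_ga_days": 280,
  "proportionality": {
   "type": "exp",
   "rate_per_day": 0.01
  },
  "covariate_effects": {
   "maternal_height_cm": {
    "per_unit": 7.8,
    "reference": 163.0
   },
   "maternal_bmi": {
    "per_unit": 9.0,
    "reference": 23.2
   },
   "parity": {
    "categories": {
     "0": 0.0,
     "1": 100.0,
     "2+": 130.0
    }
   },
   "ethnicity": {
    "categories": {
     "Caucasian": 0.0,
     "Asian": -80.0,
     "African": -35.0
    }
   },
   "fetal_sex": {
    "categories": {
     "male": 61.1,
     "female": -61.1
    }
   }
  },
  "transform": "shifted_log",
  "shift_frac": 3.997654,
  "sigma": 0.024172,
  "ga_span": [
   238,
   258
  ]
 },
 "citation": "Figueras F et al., Barcelona customized birthweight standard methodology.",
 "provenance": "synthetic-calibrated",
 "version": "1.0"
}
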