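{
 "standard_id": "msuh_cust",
 "family": "customized",
 "efw_formula_id": "hadlock4",
 "parameters": {
  "base_term_weight": 3424.4,
  "reference_ga_days": 280,
  "proportionality": {
   "type": "exp",
   "rate_per_day": 0.01
  },
  "covariate_effects": {
   "maternal_height_cm": {
    "per_unit": 7.5,
    "reference": 163.0
   },
   "paternal_height_cm": {
    "per_unit": 3.0,
    "reference": 176.0
   },
   "maternal_bmi": {
    "per_unit": 10.0,
    "reference": 23.2
   },
   "maternal_age_yr": {
    "per_unit": 1.0,
    "reference": 33.3
   },
   "parity": {
    "categories": {
     "0": 0.0,
     "1": 105.0,
     "2+": 140.0
    }
   },
   "fetal_sex": {
    "categories": {
     "male": 62.2,
     "female": -62.2
    }
   }
  },
  "transform": "shifted_log",
  "shift_frac": 5.268499,
  "sigma": 0.017518,
  "ga_span": [
   238,
   258
  ]
 },
 "citation": "Local Spanish university-hospital standard with Gardosi-style customization.",
 "provenance": "synthetic-calibrated",
 "version": "1.0"
}
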