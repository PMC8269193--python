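{
  "formula_id": "hadlock4",
  "form": "log10_linear",
  "units": "cm",
  "required_measurements": ["bpd", "hc", "ac", "fl"],
  "coefficients": {"intercept": 1.3596},
  "terms": [
    {"coef": 0.0064, "vars": ["hc"]},
    {"coef": 0.0424, "vars": ["ac"]},
    {"coef": 0.174, "vars": ["fl"]},
    {"coef": 0.00061, "vars": ["bpd", "ac"]},
    {"coef": -0.00386, "vars": ["ac", "fl"]}
  ],
  "citation": "Hadlock FP et al. Estimation of fetal weight with the use of head, body, and femur measurements - a prospective study. Am J Obstet Gynecol 1985;151:333-337 (model with BPD, HC, AC, FL).",
  "version": "1.0"
}
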