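{
  "formula_id": "hadlock3",
  "form": "log10_linear",
  "units": "cm",
  "required_measurements": ["hc", "ac", "fl"],
  "coefficients": {"intercept": 1.326},
  "terms": [
    {"coef": 0.0107, "vars": ["hc"]},
    {"coef": 0.0438, "vars": ["ac"]},
    {"coef": 0.158, "vars": ["fl"]},
    {"coef": -0.00326, "vars": ["ac", "fl"]}
  ],
  "citation": "Hadlock FP et al. Am J Obstet Gynecol 1985;151:333-337 (model with HC, AC, FL).",
  "version": "1.0"
}
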