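{
  "formula_id": "stirnemann",
  "form": "stirnemann_hc_ac",
  "units": "cm",
  "required_measurements": ["hc", "ac"],
  "coefficients": {
    "c0": 5.08482,
    "c_ac3": -54.06633,
    "c_ac3_log": -95.80076,
    "c_hc": 3.13637
  },
  "citation": "Stirnemann J et al. International estimated fetal weight standards of the INTERGROWTH-21st Project. Ultrasound Obstet Gynecol 2017;49:478-486 (HC+AC model).",
  "version": "1.0"
}
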