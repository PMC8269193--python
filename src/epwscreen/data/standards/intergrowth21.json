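{
 "standard_id": "intergrowth21",
 "family": "zscore_curve",
 "efw_formula_id": "stirnemann",
 "parameters": {
  "median_curve": {
   "ga_days": [
    238,
    239,
    240,
    241,
    242,
    243,
    244,
    245,
    246,
    247,
    248,
    249,
    250,
    251,
    252,
    253,
    254,
    255,
    256,
    257,
    258
   ],
   "median_g": [
    2215.32,
    2238.6,
    2262.1,
    2285.84,
    2309.81,
    2334.02,
    2358.45,
    2383.12,
    2408.02,
    2433.14,
    2458.5,
    2484.1,
    2509.91,
    2535.96,
    2562.24,
    2588.74,
    2615.47,
    2642.42,
    2669.59,
    2696.98,
    2724.58
   ]
  },
  "transform": "shifted_log",
  "shift_frac": 0.336445,
  "sigma": 0.092901
 },
 "citation": "Papageorghiou A / Stirnemann J et al., INTERGROWTH-21st Project.",
 "provenance": "synthetic-calibrated",
 "version": "1.0"
}
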