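{
 "standard_id": "msuh_nc",
 "family": "zscore_curve",
 "efw_formula_id": "hadlock4",
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
    2288.04,
    2311.04,
    2334.26,
    2357.72,
    2381.42,
    2405.35,
    2429.53,
    2453.94,
    2478.61,
    2503.52,
    2528.68,
    2554.09,
    2579.76,
    2605.69,
    2631.88,
    2658.33,
    2685.04,
    2712.03,
    2739.28,
    2766.81,
    2794.62
   ]
  },
  "transform": "shifted_log",
  "shift_frac": 314.192263,
  "sigma": 0.000339
 },
 "citation": "Local Spanish university-hospital population standard (non-customized form).",
 "provenance": "synthetic-calibrated",
 "version": "1.0"
}
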