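{
 "standard_id": "fmf",
 "family": "zscore_curve",
 "efw_formula_id": "hadlock3",
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
    2368.95,
    2392.47,
    2416.22,
    2440.21,
    2464.43,
    2488.89,
    2513.58,
    2538.53,
    2563.71,
    2589.15,
    2614.83,
    2640.77,
    2666.96,
    2693.41,
    2720.12,
    2747.09,
    2774.32,
    2801.83,
    2829.6,
    2857.64,
    2885.96
   ]
  },
  "transform": "shifted_log",
  "shift_frac": -0.062035,
  "sigma": 0.094358
 },
 "citation": "Nicolaides KH et al., Fetal Medicine Foundation fetal growth model.",
 "provenance": "synthetic-calibrated",
 "version": "1.0"
}
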