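{
 "standard_id": "who",
 "family": "quantile_grid",
 "efw_formula_id": "hadlock4",
 "parameters": {
  "ga_days": [
   238,
   245,
   252,
   259
  ],
  "levels": [
   5,
   10,
   25,
   50,
   75,
   90,
   95
  ],
  "weights_g": [
   [
    1956.72,
    2033.03,
    2168.88,
    2350.88,
    2655.62,
    2964.19,
    3163.51
   ],
   [
    2098.6,
    2180.44,
    2326.14,
    2521.34,
    2848.17,
    3179.12,
    3392.89
   ],
   [
    2250.76,
    2338.54,
    2494.81,
    2704.15,
    3054.69,
    3409.63,
    3638.9
   ],
   [
    2413.96,
    2508.1,
    2675.7,
    2900.23,
    3276.18,
    3656.85,
    3902.75
   ]
  ]
 },
 "citation": "Kiserud T et al., WHO fetal growth charts.",
 "provenance": "synthetic-calibrated",
 "version": "1.0"
}
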