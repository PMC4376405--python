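{
 "energy_kcal_day": 2615.2,
 "protein_g_day": 64.0,
 "carbohydrate_g_day": 65.0,
 "fat_g_day": 58.12,
 "amino_acids_g_day": {
  "lys": 3.26,
  "leu": 3.52,
  "val": 2.05,
  "his": 1.15,
  "trp": 0.45,
  "thr": 1.73,
  "ile": 1.6,
  "met_cys": 1.6,
  "phe_tyr": 3.01
 }
}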