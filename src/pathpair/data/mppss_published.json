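{
 "entries": [
  {"pair": "hsa00100-hsa00190", "coef": 1.0285978},
  {"pair": "hsa00563-hsa00190", "coef": 1.4211556},
  {"pair": "hsa00534-hsa00190", "coef": 1.0289191},
  {"pair": "hsa00900-hsa00190", "coef": 1.1686399},
  {"pair": "hsa00310-hsa00534", "coef": -0.6982631},
  {"pair": "hsa00760-hsa00190", "coef": 1.1373381},
  {"pair": "hsa00531-hsa00860", "coef": 0.1188049},
  {"pair": "hsa00513-hsa00620", "coef": 1.3416181},
  {"pair": "hsa01040-hsa00190", "coef": 1.0216412},
  {"pair": "hsa00310-hsa00600", "coef": -0.8491503},
  {"pair": "hsa00534-hsa00620", "coef": 0.1976417},
  {"pair": "hsa00310-hsa00531", "coef": -1.1770501},
  {"pair": "hsa00051-hsa00860", "coef": 0.4476219}
 ],
 "intercept": 0.0,
 "representation": "continuous",
 "provenance": "Published 13-pair blood diagnostic model for Alzheimer's disease (KEGG metabolism pathway pairs, L1-logistic coefficients as printed; no intercept was published). Whether the published coefficients apply to continuous activity differences or to the +/-1 ordering indicator is ambiguous in the source; this file marks them continuous."
}
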