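{
 "intercept": 0.0,
 "representation": "microarray-log2",
 "weights": {
  "ILMN_1664047": 0.955,
  "ILMN_1790100": 0.844,
  "ILMN_1701837": 0.789,
  "ILMN_1684497": 0.727,
  "ILMN_1775380": 0.675,
  "ILMN_1802888": 0.646,
  "ILMN_3236239": 0.561,
  "ILMN_1796423": 0.464,
  "ILMN_1801216": -0.405,
  "ILMN_2058782": -0.426,
  "ILMN_1898691": -0.599,
  "ILMN_2379599": -0.638,
  "ILMN_1756928": -0.69
 }
}
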