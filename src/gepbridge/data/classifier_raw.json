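{
 "intercept": 23.972,
 "representation": "raw-dct",
 "weights": {
  "CACNA1E": 0.426,
  "KLHL2": 0.945,
  "PYROXD2": 0.302,
  "SMOX": 0.898,
  "ZNF185": 0.051,
  "LINC02035": 0.382,
  "CLIC3": 0.129,
  "S100P": 0.179,
  "IFI27": -0.298,
  "TIGIT": -0.193,
  "CD163": -1.249,
  "RTN1": -0.873
 }
}
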