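{
 "intercept": 21.72,
 "representation": "normalized-dct",
 "weights": {
  "CACNA1E": 0.746,
  "KLHL2": 1.227,
  "PYROXD2": 0.347,
  "SMOX": 1.061,
  "ZNF185": 0.044,
  "LINC02035": 0.776,
  "CLIC3": 0.161,
  "S100P": 0.379,
  "IFI27": -1.138,
  "TIGIT": -0.196,
  "CD163": -1.87,
  "RTN1": -0.905
 },
 "norm": {
  "CACNA1E": {"mean": -4.763, "sd": 1.751},
  "KLHL2": {"mean": -0.865, "sd": 1.299},
  "PYROXD2": {"mean": -4.385, "sd": 1.149},
  "SMOX": {"mean": -1.885, "sd": 1.182},
  "ZNF185": {"mean": -1.185, "sd": 0.863},
  "LINC02035": {"mean": -3.382, "sd": 2.029},
  "CLIC3": {"mean": -2.69, "sd": 1.244},
  "S100P": {"mean": 0.591, "sd": 2.114},
  "IFI27": {"mean": -0.309, "sd": 3.819},
  "TIGIT": {"mean": -2.959, "sd": 1.014},
  "CD163": {"mean": -1.791, "sd": 1.497},
  "RTN1": {"mean": -2.643, "sd": 1.037}
 }
}
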