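{
  "analyte": "cHb",
  "unit": "g/dL",
  "parameters": [-0.3409, 0.83, -0.0093, 0.0003, 0.0058],
  "offset": 3.76,
  "domain_ga": [22.0, 42.0],
  "domain_pna": [0.0, 28.0],
  "provenance": "published tied bi-quadratic fit, GA 22-42 wk, PNA 0-28 d"
}
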