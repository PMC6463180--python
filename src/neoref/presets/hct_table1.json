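{
  "analyte": "Hct",
  "unit": "%",
  "parameters": [-1.2956, 2.5369, -0.03, 0.0069, 0.019],
  "offset": 10.69,
  "domain_ga": [22.0, 42.0],
  "domain_pna": [0.0, 28.0],
  "provenance": "published tied bi-quadratic fit, GA 22-42 wk, PNA 0-28 d"
}
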