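"""Look up a reference band and flag a measured value against it.

A neonate born at 30 weeks gestation, now 7 days old, has a measured
hemoglobin concentration of 11.2 g/dL.  The script prints the mean and
5th–95th percentile reference values at that age and where the
measurement falls relative to the band.
"""

import neoref as nr

model = nr.chb_reference_model()
band = nr.evaluate_band(model, ga=30, pna=7)
print(f"cHb reference at GA 30 wk, PNA 7 d: "
      f"mean {band.mean:.2f} {model.unit}, "
      f"5th-95th percentile [{band.p5:.2f}, {band.p95:.2f}]")

obs = nr.Observation(id="case-1", ga=30, pna=7, analyte="chb", value=11.2)
flag, _ = nr.classify(model, obs)
print(f"measured {obs.value} {model.unit} -> {flag.value}")
# 'within' means the value lies inside the central 90% of clinically
# stable neonates of the same gestational and postnatal age; 'below'
# would be a value under the 5th percentile (possible anemia).
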