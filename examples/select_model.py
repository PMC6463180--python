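"""Scan the polynomial term library and print the accuracy-complexity
Pareto front.

Fits every admissible subset of {1, PNA, (1+PNA) tied, GA, GA^2,
GA*PNA, PNA^2} to a noise-free cHb grid and lists the non-dominated
candidates.  The 5-parameter tied bi-quadratic is the smallest model
reaching (numerically) zero error, which is why that form ships as the
preset.
"""

import neoref as nr

data = nr.generate_grid(nr.chb_reference_model())
candidates = nr.enumerate_candidates(data, max_params=7)
front = nr.pareto_front(candidates)

print(f"{len(candidates)} candidate models fitted; Pareto front:")
for c in front:
    print(f"  {c.n_params} params  sse={c.sse:10.4g}  mask={c.mask}")
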