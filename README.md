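# neoref

Age-dependent reference ranges for neonatal hemoglobin concentration
(cHb) and hematocrit (Hct), for neonatologists, laboratory scientists
and anyone building decision support on top of a complete blood count.

A neonate's "normal" cHb and Hct depend jointly on gestational age at
birth (GA) and postnatal age (PNA): both analytes rise with GA and fall
over the first weeks of life. Most lookup tables condition on only one
of the two. `neoref` implements a smooth two-variable model covering
GA 22–42 weeks and PNA 0–28 days, and the machinery to refit, stress
and validate it.

## The model

The mean reference value is a *tied bi-quadratic* surface with five
free parameters:

```
mean(GA, PNA) = p1·(1 + PNA) + p2·GA + p3·GA² + p4·GA·PNA + p5·PNA²
```

p1 is tied: one coefficient serves as both the intercept and the
linear-PNA slope. The 5th and 95th percentile surfaces are the mean
shifted by a constant offset (γ = 3.76 g/dL for cHb, λ = 10.69 % for
Hct), so the reference band has constant width 2·offset everywhere.
Shipped coefficients:

| analyte | p1 | p2 | p3 | p4 | p5 | offset |
|---|---|---|---|---|---|---|
| cHb (g/dL) | −0.3409 | 0.8300 | −0.0093 | 0.0003 | 0.0058 | 3.76 |
| Hct (%) | −1.2956 | 2.5369 | −0.0300 | 0.0069 | 0.0190 | 10.69 |

Beyond evaluation and classification the package refits the surface
from gridded data (closed-form least squares, with a Levenberg–
Marquardt path as a cross-check), estimates the percentile offset,
scans all subsets of a 7-term polynomial library to exhibit the
accuracy–complexity Pareto front on which the 5-parameter form sits,
computes validation statistics (mean absolute error, band coverage),
and generates the synthetic grids and cohorts its own tests run on.

## Worked example

```python
import neoref as nr

model = nr.chb_reference_model()
band = nr.evaluate_band(model, ga=30, pna=7)
obs = nr.Observation(id="case-1", ga=30, pna=7, analyte="chb", value=11.2)
flag, _ = nr.classify(model, obs)
```

prints, via `python examples/lookup_and_classify.py`:

```
cHb reference at GA 30 wk, PNA 7 d: mean 14.15 g/dL, 5th-95th percentile [10.39, 17.91]
measured 11.2 g/dL -> within
```

The mean reference cHb for a neonate born at 30 weeks, on day 7 of
life, is 14.15 g/dL; the central 90% of clinically stable neonates of
that age fall between 10.39 and 17.91 g/dL, so the measured 11.2 g/dL
is unremarkable. A value below 10.39 would flag as `below` (possible
anemia). The other scripts in `examples/` demonstrate refitting
(`refit_from_grid.py`), model selection (`select_model.py`) and cohort
validation (`validate_cohort.py`); each prints the numbers it computes
and a line on what they mean.

A thin CLI wraps the same operations:

```
neoref lookup --analyte chb --ga 40 --pna 0
neoref refit --grid grid.csv --method lm
neoref validate --analyte hct --cohort cohort.csv
neoref export --analyte chb --out table.csv --round 2
```

## Caveats

The percentile band is symmetric and of constant width by construction
— this is a modelling choice, not an LMS/GAMLSS-style percentile fit.
The shipped Hct surface slightly *rises* with PNA in the extreme
high-GA/high-PNA corner of the domain (see `docs/methods.md`). Queries
outside GA 22–42 wk / PNA 0–28 d are evaluated but flagged as
extrapolations.
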