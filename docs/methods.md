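# Methods

## Model

The mean reference surface for each analyte is

    mean(GA, PNA) = p1·(1 + PNA) + p2·GA + p3·GA² + p4·GA·PNA + p5·PNA²

with GA in completed weeks (valid 22–42) and PNA in days of life
(valid 0–28). The first coefficient is deliberately *tied*: it
multiplies both the constant and the linear-PNA basis term, so the
surface has five free parameters rather than six. The shipped
coefficients are carried bit-exactly as published (cHb: −0.3409,
0.8300, −0.0093, 0.0003, 0.0058 in g/dL-based units; Hct: −1.2956,
2.5369, −0.0300, 0.0069, 0.0190 in %-based units). We implement the
tied form exactly as printed and do not introduce a separate sixth
coefficient: the tied five-parameter model is self-consistent, exactly
identifiable, and is the form the selection analysis below singles
out.

The 5th and 95th percentile surfaces are the mean shifted by a single
constant (cHb: γ = 3.76 g/dL; Hct: λ = 10.69 %), reflecting an
empirically constant, symmetric spread over the age domain. The band
is therefore exactly symmetric with width 2·offset at every age — a
constant-offset construction, not a distribution-quantile fit such as
LMS/GAMLSS. Classification against the band is inclusive at both
bounds: a value exactly on the 5th or 95th percentile is `within`, so
boundary measurements are not flagged as abnormal.

GA and PNA are treated as continuous reals (fractional weeks and days
are allowed) even though source tables are integer-valued: the model
is a smooth surface. Queries outside the validity box still evaluate
(the polynomial is global) but return `extrapolated=True` and emit a
warning rather than an error — clinical queries at GA 21.9 or PNA 29
are realistic, and day 29 in particular is treated as extrapolation
rather than rejection because the valid PNA range is bounded at day 28.
Units are fixed per analyte (g/dL, %) and carried as metadata; no
conversion is attempted.

## Fitting

The tied surface is linear in its parameters on the basis
(1+PNA, GA, GA², GA·PNA, PNA²), so the least-squares problem has a
unique closed-form solution whenever the design has rank 5.
`fit_closed_form` (the default) solves it by orthogonal decomposition
(`numpy.linalg.lstsq`); rank deficiency raises an identifiability
error that names the inestimable basis directions (from the SVD null
space). `fit_lm` minimises the same sum of squares with
Levenberg–Marquardt (`scipy.optimize.least_squares`, method `"lm"`,
numerically estimated Jacobian) over the model's prediction function.
Defaults: zero initial vector, `tol=1e-10` applied to the step, cost
and gradient criteria, `max_iter=200` function evaluations. Because
the model is linear in parameters, initialisation is immaterial and
the two routes must agree; the test suite asserts coefficient-wise
agreement to 1e−6 on randomized noisy datasets, which makes the pair a
permanent internal cross-check. Fitting is unweighted: all grid
records count equally.

The percentile offset is estimated as the pooled mean of all available
half-spreads, (mean − p5) and (p95 − mean) — the least-squares
constant under a symmetric band. Where a record's mean is missing, the
fitted mean from the supplied surface is substituted. The two-stage
order (fit the mean surface first, then the offset) mirrors the
construction of the model; on self-consistent symmetric data the
estimator returns the generating offset exactly.

## Model selection

The functional form is justified by an exhaustive scan instead of the
original (proprietary, unreproducible) genetic-programming symbolic
regression: every admissible subset of the term library {1, PNA,
(1+PNA) tied, GA, GA², GA·PNA, PNA²} is fitted by closed-form least
squares. The tied term is mutually exclusive with the separate
intercept and linear-PNA terms, giving 79 admissible subsets — small
enough that exhaustive search dominates any stochastic one. Complexity
is the count of free coefficients; accuracy is in-sample SSE. The
reported Pareto front contains the candidates not dominated on
(n_params, sse), sorted by size, with exact ties resolved to the
lexicographically smallest mask. Rank-deficient candidates (e.g.
GA·PNA on a PNA = 0 slice) are skipped with a log entry. The term
library is an assumption of this package: only polynomial terms up to
degree 2 per variable are considered, as the final model form is
polynomial.

## Validation statistics

`mae_against_grid` is the mean absolute deviation between the fitted
mean surface and a grid's mean values. `coverage` classifies each
cohort observation against the 5th–95th band and reports below/within/
above tallies and the within-fraction, per analyte, with a pooling
helper for joint tallies across analytes. Observations marked
post-transfusion are kept by default (with a logged note) and can be
excluded with a flag, since transfusion moves cHb/Hct off the
reference distribution. No hypothesis test is attached to coverage.

## Synthetic data

No machine-readable version of the source reference tables or the
clinical validation cohort is published, so all test inputs are
synthesized from a reference model.

*Grids* emulate the digitized source tables: 77 records per analyte by
default — a GA sweep over integer weeks 22–42 at PNA 0 (21 points)
plus PNA sweeps over days 1–28 at GA 30 and GA 40 (2×28 points). The
decomposition matches how the source material slices the data (cHb/Hct
against GA, and against PNA at representative gestations) and the
published per-analyte record count; the true layout is not published,
so the layout is configurable (arbitrary cartesian or paired point
sets). Mean values are the surface plus optional Gaussian noise
(`sd_mean`); percentile columns are mean ∓/± offset plus independent
Gaussian noise (`sd_band`, default 0), which also lets tests probe the
offset estimator's response to asymmetric bands. Records whose noisy
band inverts are re-ordered by sorting the (p5, mean, p95) triple, and
the count is logged. Defaults are noise-free: the generator's first
job is exact-recovery testing.

*Cohorts* emulate the published clinical validation sample:
n = 19, GA ~ N(33.91, 1.73²) weeks truncated to the model's GA domain,
PNA ~ N(8.26, 7.31²) days truncated at 0 (rejection sampling;
optionally rounded to whole days). Measured values are the surface
mean plus N(0, value_sd²), redrawn if nonpositive. `value_sd` defaults
to offset/1.644854 (the 0.95 normal quantile), which makes the model's
band the central-90% interval of the measurement distribution — the
natural calibration for coverage tests, and the one the Monte-Carlo
acceptance check (coverage ∈ [0.88, 0.92] at n = 5000) relies on.
Everything is deterministic under a fixed seed.

What the generator does *not* emulate: digitization error of the
source figures, non-Gaussian or age-heteroscedastic measurement
spread, asymmetric percentiles in the source data, transfusion
physiology, phlebotomy loss, or capillary-vs-venous offsets. Passing
recovery and calibration tests therefore demonstrates correctness of
the estimators under the stated model, not fidelity of the model to
any particular hospital's population.

## Numerical choices and problem sizes

Rank is judged against the SVD tolerance `s_max · max(n,5) · eps`.
Exact-recovery assertions use 1e−6 absolute per coefficient;
self-consistency (MAE = 0, band width 2·offset) is asserted to
1e−12. The dense trend-check grid uses a 0.1-week × 0.1-day step
(201 × 281 points, vectorized). Statistical tests use fixed seeds:
cross-route agreement over 50 randomized datasets, coverage
calibration at n = 5000, moment checks at n = 5000 against analytic
truncated-normal moments, and a 1/√n RMSE-shrinkage check with 40
replicates at grid replications 1 and 16. These sizes keep the whole
suite in the seconds range while leaving the statistical assertions
with comfortable margins.

## Known limitations

* **Hct PNA-trend violation.** The published Hct coefficients imply
  d/dPNA = p1 + p4·GA + 2·p5·PNA = +0.058 %/day at GA 42, PNA 28: the
  fitted surface *rises* with PNA in the extreme high-GA/high-PNA
  corner (roughly GA ≳ 40 with PNA ≳ 26.5), against the physiological
  expectation that cHb and Hct decline over the first month. This is a
  property of the published quadratic itself, faithfully reproduced
  here; the cHb surface is monotone throughout (its corner margin is a
  thin −0.0035 g/dL/day). The test suite asserts the strict
  both-analyte trend claim as stated, so that check fails on the Hct
  corner by design rather than being weakened.
* The constant, symmetric band cannot represent age-varying or skewed
  spread; values near the band edge at extreme ages should be read
  with that in mind.
* Published headline validation figures (MAE against the source grid;
  cohort coverage) depend on unpublished data and are not reproduced;
  the corresponding operations are instead verified on constructed
  inputs with known answers.
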