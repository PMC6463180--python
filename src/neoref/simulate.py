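"""Synthetic reference grids and clinical cohorts.

No machine-readable version of the source reference data is published,
so tests and demonstrations run on synthetic stand-ins generated from a
reference model:

* a *grid* of (GA, PNA) points carrying mean and 5th/95th percentile
  values — the shape of the digitized source tables.  The default
  layout has 77 records per analyte: a GA sweep over integer weeks
  22–42 at PNA 0 (21 points) plus PNA sweeps over days 1–28 at GA 30
  and GA 40 (2×28 points), mirroring how the source figures slice the
  data by GA-dependence and PNA-dependence;
* a *cohort* of individual neonates with GA ~ N(33.91, 1.73²) weeks
  (truncated to the model's GA domain) and PNA ~ N(8.26, 7.31²) days
  (truncated at 0), n = 19 by default — the published summary of the
  clinical validation sample.

Both are deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError, UsageError
from .fitting import GridDataset
from .model import Observation, ReferenceModel, evaluate_mean

logger = logging.getLogger(__name__)

__all__ = ["NoiseSpec", "CohortSpec", "default_layout", "generate_grid",
           "generate_cohort"]

#: z-quantile of the standard normal at 0.95 — a band of half-width
#: z*sd around the mean covers the central 90% of N(mean, sd²)
Z_90 = 1.644854


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian perturbations applied to a generated grid."""

    sd_mean: float = 0.0   # sd on the mean column, analyte units
    sd_band: float = 0.0   # independent sd on each percentile column
    seed: int = 0

    def __post_init__(self):
        if self.sd_mean < 0 or self.sd_band < 0:
            raise InvalidInputError("noise sds must be nonnegative")


@dataclass(frozen=True)
class CohortSpec:
    """Sampling plan for a synthetic clinical cohort.

    Defaults reproduce the published validation-sample summary
    (n = 19, GA 33.91 ± 1.73 wk, PNA 8.26 ± 7.31 d).  ``value_sd`` is
    the spread of measured values about the mean surface; ``None``
    selects offset/1.644854, which makes the model's 5th–95th band the
    central 90% interval of the measurement distribution.
    """

    n: int = 19
    ga_mean: float = 33.91
    ga_sd: float = 1.73
    pna_mean: float = 8.26
    pna_sd: float = 7.31
    value_sd: float | None = None
    seed: int = 0
    round_pna: bool = False

    def __post_init__(self):
        if self.n < 1:
            raise InvalidInputError(f"cohort size must be >= 1, got {self.n}")
        for name in ("ga_sd", "pna_sd"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be nonnegative")
        if self.value_sd is not None and self.value_sd < 0:
            raise InvalidInputError("value_sd must be nonnegative")


def default_layout() -> tuple[np.ndarray, np.ndarray]:
    """Paired (ga, pna) arrays of the 77-point default grid layout."""
    ga_sweep = np.arange(22.0, 43.0)                  # 21 points at PNA 0
    pna_sweep = np.arange(1.0, 29.0)                  # days 1..28
    ga = np.concatenate([ga_sweep,
                         np.full_like(pna_sweep, 30.0),
                         np.full_like(pna_sweep, 40.0)])
    pna = np.concatenate([np.zeros_like(ga_sweep), pna_sweep, pna_sweep])
    return ga, pna


def generate_grid(model: ReferenceModel,
                  ga_values=None, pna_values=None,
                  noise: NoiseSpec | None = None,
                  cartesian: bool = True) -> GridDataset:
    """Synthesize a reference grid from a model.

    With ``ga_values``/``pna_values`` given and ``cartesian=True`` the
    grid is their product; with ``cartesian=False`` they are paired
    point lists of equal length.  With neither given, the 77-point
    default layout is used.  Mean values are evaluate_mean + N(0,
    sd_mean); percentiles are mean ∓/± offset with independent N(0,
    sd_band) noise.  Records whose noisy band inverts (p5 > mean or
    mean > p95) are re-ordered by sorting the triple; the count is
    logged.
    """
    noise = noise or NoiseSpec()
    if (ga_values is None) != (pna_values is None):
        raise UsageError("provide both ga_values and pna_values, or neither")
    if ga_values is None:
        ga, pna = default_layout()
    else:
        ga = np.asarray(ga_values, dtype=float)
        pna = np.asarray(pna_values, dtype=float)
        if ga.size == 0 or pna.size == 0:
            raise UsageError("ga_values and pna_values must be nonempty")
        if cartesian:
            ga, pna = (a.ravel() for a in np.meshgrid(ga, pna,
                                                      indexing="ij"))
        elif len(ga) != len(pna):
            raise UsageError("paired ga_values and pna_values must have "
                             "equal length")
    rng = np.random.default_rng(noise.seed)
    mean = evaluate_mean(model.surface, ga, pna)
    mean = mean + rng.normal(0.0, noise.sd_mean, size=len(ga)) \
        if noise.sd_mean > 0 else np.asarray(mean, dtype=float)
    p5 = mean - model.offset
    p95 = mean + model.offset
    if noise.sd_band > 0:
        p5 = p5 + rng.normal(0.0, noise.sd_band, size=len(ga))
        p95 = p95 + rng.normal(0.0, noise.sd_band, size=len(ga))
    stacked = np.sort(np.column_stack([p5, mean, p95]), axis=1)
    n_reordered = int(np.sum(np.any(
        stacked != np.column_stack([p5, mean, p95]), axis=1)))
    if n_reordered:
        logger.info("re-ordered %d record(s) whose noisy band inverted",
                    n_reordered)
    p5, mean, p95 = stacked[:, 0], stacked[:, 1], stacked[:, 2]
    return GridDataset(ga=ga, pna=pna, mean=mean, p5=p5, p95=p95,
                       analyte=model.analyte)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float, n: int) -> np.ndarray:
    """Rejection sampling of N(mean, sd²) restricted to [low, high]."""
    if sd == 0:
        if not (low <= mean <= high):
            raise InvalidInputError(
                f"degenerate distribution at {mean} lies outside "
                f"[{low}, {high}]")
        return np.full(n, float(mean))
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 16))
        keep = draw[(draw >= low) & (draw <= high)]
        take = min(len(keep), n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def generate_cohort(model: ReferenceModel,
                    spec: CohortSpec | None = None) -> list[Observation]:
    """Synthesize a clinical cohort of individual observations.

    Values are drawn as evaluate_mean(GA, PNA) + N(0, value_sd); draws
    that are nonpositive (physically impossible) are redrawn.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    value_sd = (model.offset / Z_90 if spec.value_sd is None
                else spec.value_sd)
    ga = _truncated_normal(rng, spec.ga_mean, spec.ga_sd,
                           model.domain_ga[0], model.domain_ga[1], spec.n)
    pna = _truncated_normal(rng, spec.pna_mean, spec.pna_sd,
                            0.0, np.inf, spec.n)
    if spec.round_pna:
        pna = np.round(pna)
    mean = evaluate_mean(model.surface, ga, pna)
    value = mean + rng.normal(0.0, value_sd, size=spec.n)
    bad = value <= 0
    while np.any(bad):
        value[bad] = mean[bad] + rng.normal(0.0, value_sd,
                                            size=int(bad.sum()))
        bad = value <= 0
    return [Observation(id=f"sim-{i:04d}", ga=float(ga[i]),
                        pna=float(pna[i]), analyte=model.analyte,
                        value=float(value[i]))
            for i in range(spec.n)]
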