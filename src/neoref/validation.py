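"""Validation statistics: mean-surface MAE and percentile-band coverage.

Two checks quantify how well a reference model describes data it did not
define: the mean absolute error between the fitted mean surface and a
grid of observed means, and the fraction of a clinical cohort's values
falling inside the model's 5th–95th percentile band.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import MissingDataError, UsageError
from .fitting import GridDataset
from .model import Flag, Observation, ReferenceModel, classify, evaluate_mean

logger = logging.getLogger(__name__)

__all__ = ["ValidationReport", "mae_against_grid", "coverage",
           "pooled_report"]


@dataclass(frozen=True)
class ValidationReport:
    """Tallies of a cohort against a reference band, plus optional MAE."""

    analyte: str
    n_observations: int
    n_below: int
    n_within: int
    n_above: int
    coverage_fraction: float
    n_excluded: int = 0
    mae_mean_surface: float | None = None
    n_grid_points: int = 0

    def __post_init__(self):
        if self.n_below + self.n_within + self.n_above != self.n_observations:
            raise ValueError("tallies do not sum to n_observations")

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    def to_text(self) -> str:
        lines = [f"Validation report ({self.analyte})"]
        if self.mae_mean_surface is not None:
            lines.append(f"  mean-surface MAE: {self.mae_mean_surface:.6f} "
                         f"over {self.n_grid_points} grid points")
        lines += [
            f"  cohort: {self.n_observations} observations"
            + (f" ({self.n_excluded} excluded)" if self.n_excluded else ""),
            f"  below band:  {self.n_below}",
            f"  within band: {self.n_within}",
            f"  above band:  {self.n_above}",
            f"  coverage: {100.0 * self.coverage_fraction:.1f}%",
        ]
        return "\n".join(lines)


def mae_against_grid(model: ReferenceModel, data: GridDataset) -> float:
    """Mean absolute error of the mean surface against grid means."""
    keep = np.isfinite(data.mean)
    if len(data) == 0 or not np.any(keep):
        raise MissingDataError("grid dataset has no mean values")
    pred = evaluate_mean(model.surface, data.ga[keep], data.pna[keep])
    return float(np.mean(np.abs(pred - data.mean[keep])))


def coverage(model: ReferenceModel, cohort: list[Observation],
             exclude_post_transfusion: bool = False,
             grid: GridDataset | None = None) -> ValidationReport:
    """Classify each observation and tally band coverage.

    Post-transfusion observations are kept by default (with a logged
    note); set ``exclude_post_transfusion=True`` to drop them.  When a
    ``grid`` is supplied, the mean-surface MAE is reported alongside.
    """
    if not cohort:
        raise MissingDataError("cohort is empty")
    mismatched = [o for o in cohort if o.analyte is not model.analyte]
    if mismatched:
        raise UsageError(
            f"{len(mismatched)} observation(s) have analyte "
            f"{mismatched[0].analyte.value}, model expects "
            f"{model.analyte.value}")
    flagged = [o for o in cohort if o.post_transfusion]
    if flagged and not exclude_post_transfusion:
        logger.info("cohort contains %d post-transfusion observation(s); "
                    "kept (pass exclude_post_transfusion=True to drop)",
                    len(flagged))
    used = [o for o in cohort if not (exclude_post_transfusion
                                      and o.post_transfusion)]
    if not used:
        raise MissingDataError("all observations were excluded")
    tallies = {Flag.BELOW: 0, Flag.WITHIN: 0, Flag.ABOVE: 0}
    for obs in used:
        flag, _ = classify(model, obs, warn=False)
        tallies[flag] += 1
    mae = n_grid = None
    if grid is not None:
        mae = mae_against_grid(model, grid)
        n_grid = int(np.sum(np.isfinite(grid.mean)))
    return ValidationReport(
        analyte=model.analyte.value,
        n_observations=len(used),
        n_below=tallies[Flag.BELOW],
        n_within=tallies[Flag.WITHIN],
        n_above=tallies[Flag.ABOVE],
        coverage_fraction=tallies[Flag.WITHIN] / len(used),
        n_excluded=len(cohort) - len(used),
        mae_mean_surface=mae,
        n_grid_points=n_grid or 0)


def pooled_report(reports: list[ValidationReport]) -> ValidationReport:
    """Pool per-analyte tallies into one joint coverage figure."""
    if not reports:
        raise MissingDataError("no reports to pool")
    n = sum(r.n_observations for r in reports)
    below = sum(r.n_below for r in reports)
    within = sum(r.n_within for r in reports)
    above = sum(r.n_above for r in reports)
    return ValidationReport(
        analyte="+".join(r.analyte for r in reports),
        n_observations=n, n_below=below, n_within=within, n_above=above,
        coverage_fraction=within / n,
        n_excluded=sum(r.n_excluded for r in reports))
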