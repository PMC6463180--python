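"""Refitting the tied bi-quadratic surface and the percentile offset.

The tied surface is *linear in its five parameters*, so ordinary least
squares on the design basis (1 + PNA, GA, GA², GA·PNA, PNA²) gives the
unique solution in closed form.  A Levenberg–Marquardt path over the
model's prediction function is provided as well; for this model it must
converge to the closed-form solution from any finite start, which makes
the two routes a built-in cross-check.

The percentile offset (the constant band half-width) is estimated as the
pooled mean of the available half-spreads mean−p5 and p95−mean, which is
the least-squares constant under a symmetric band.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import (ConvergenceError, IdentifiabilityError,
                         InvalidInputError, MissingDataError)
from .model import Analyte, SurfaceParameters, evaluate_mean

__all__ = [
    "GridDataset",
    "FitResult",
    "FitMethod",
    "design_row",
    "design_matrix",
    "fit_closed_form",
    "fit_lm",
    "estimate_offset",
]

#: names of the five basis terms, in coefficient order p1..p5
BASIS_TERMS = ("1+PNA", "GA", "GA^2", "GA*PNA", "PNA^2")

GRID_COLUMNS = ("ga_weeks", "pna_days", "mean", "p5", "p95")


@dataclass
class GridDataset:
    """(GA, PNA) grid with mean and optional 5th/95th percentile values.

    Missing entries (mean or percentiles) are NaN.  Where present, each
    record must satisfy p5 <= mean <= p95.
    """

    ga: np.ndarray
    pna: np.ndarray
    mean: np.ndarray
    p5: np.ndarray = None
    p95: np.ndarray = None
    analyte: Analyte = Analyte.CHB

    def __post_init__(self):
        self.ga = np.asarray(self.ga, dtype=float)
        self.pna = np.asarray(self.pna, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        n = len(self.ga)
        if self.p5 is None:
            self.p5 = np.full(n, np.nan)
        if self.p95 is None:
            self.p95 = np.full(n, np.nan)
        self.p5 = np.asarray(self.p5, dtype=float)
        self.p95 = np.asarray(self.p95, dtype=float)
        self.analyte = Analyte.parse(self.analyte)
        for name in ("pna", "mean", "p5", "p95"):
            if len(getattr(self, name)) != n:
                raise InvalidInputError(
                    f"column {name} has length {len(getattr(self, name))}, "
                    f"expected {n}")
        low = self.p5[np.isfinite(self.p5) & np.isfinite(self.mean)]
        mid_lo = self.mean[np.isfinite(self.p5) & np.isfinite(self.mean)]
        if np.any(low > mid_lo + 1e-12):
            raise InvalidInputError("some records have p5 > mean")
        hi = self.p95[np.isfinite(self.p95) & np.isfinite(self.mean)]
        mid_hi = self.mean[np.isfinite(self.p95) & np.isfinite(self.mean)]
        if np.any(hi < mid_hi - 1e-12):
            raise InvalidInputError("some records have p95 < mean")

    def __len__(self) -> int:
        return len(self.ga)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "ga_weeks": self.ga, "pna_days": self.pna,
            "mean": self.mean, "p5": self.p5, "p95": self.p95})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   analyte: "str | Analyte" = Analyte.CHB) -> "GridDataset":
        return cls(ga=frame["ga_weeks"].to_numpy(float),
                   pna=frame["pna_days"].to_numpy(float),
                   mean=frame["mean"].to_numpy(float),
                   p5=frame["p5"].to_numpy(float) if "p5" in frame else None,
                   p95=frame["p95"].to_numpy(float) if "p95" in frame
                   else None,
                   analyte=analyte)


class FitMethod(str, enum.Enum):
    CLOSED_FORM = "closed_form"
    LEVENBERG_MARQUARDT = "levenberg_marquardt"


@dataclass(frozen=True)
class FitResult:
    """Recovered surface plus residual diagnostics and convergence record."""

    surface: SurfaceParameters
    sse: float
    mae_insample: float
    n_points: int
    converged: bool
    n_iterations: int
    method: FitMethod
    offset: float | None = None


def design_row(ga: float, pna: float) -> np.ndarray:
    """The 5 regressors at one (ga, pna), in coefficient order p1..p5.

    The first regressor is (1 + pna): it encodes the tied coefficient
    that serves as both intercept and linear-PNA slope.
    """
    row = design_matrix(np.atleast_1d(ga), np.atleast_1d(pna))
    return row[0]


def design_matrix(ga, pna) -> np.ndarray:
    """Stacked design rows, shape (n, 5)."""
    ga = np.asarray(ga, dtype=float)
    pna = np.asarray(pna, dtype=float)
    if not (np.all(np.isfinite(ga)) and np.all(np.isfinite(pna))):
        raise InvalidInputError("ga and pna must be finite")
    return np.column_stack([1.0 + pna, ga, ga ** 2, ga * pna, pna ** 2])


def _mean_rows(data: GridDataset) -> tuple[np.ndarray, np.ndarray]:
    keep = np.isfinite(data.mean)
    if not np.any(keep):
        raise MissingDataError("grid dataset has no mean values to fit")
    return (design_matrix(data.ga[keep], data.pna[keep]), data.mean[keep])


def _check_rank(X: np.ndarray) -> None:
    """Raise IdentifiabilityError naming null-space directions if rank < 5."""
    if X.shape[0] < X.shape[1]:
        raise IdentifiabilityError(
            f"only {X.shape[0]} usable records for {X.shape[1]} coefficients",
            directions=list(BASIS_TERMS))
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * max(X.shape) * np.finfo(float).eps if s[0] > 0 else 0.0
    rank = int(np.sum(s > tol))
    if rank < X.shape[1]:
        directions = []
        for null_vec in vt[rank:]:
            dominant = np.argsort(-np.abs(null_vec))[:2]
            directions.append(" & ".join(BASIS_TERMS[i] for i in dominant
                                         if abs(null_vec[i]) > 1e-8))
        raise IdentifiabilityError(
            f"design matrix has rank {rank} < 5; unidentifiable "
            f"directions involve: {directions}", directions=directions)


def _diagnostics(X: np.ndarray, y: np.ndarray,
                 params: np.ndarray) -> tuple[float, float]:
    resid = y - X @ params
    return float(resid @ resid), float(np.mean(np.abs(resid)))


def fit_closed_form(data: GridDataset) -> FitResult:
    """Unique least-squares solution via orthogonal decomposition.

    Raises :class:`IdentifiabilityError` when the design is rank-deficient.
    """
    X, y = _mean_rows(data)
    _check_rank(X)
    params, *_ = np.linalg.lstsq(X, y, rcond=None)
    sse, mae = _diagnostics(X, y, params)
    return FitResult(surface=SurfaceParameters.from_array(params),
                     sse=sse, mae_insample=mae, n_points=len(y),
                     converged=True, n_iterations=0,
                     method=FitMethod.CLOSED_FORM)


def fit_lm(data: GridDataset, init: SurfaceParameters | None = None,
           tol: float = 1e-10, max_iter: int = 200) -> FitResult:
    """Levenberg–Marquardt minimisation of the sum of squared residuals.

    The objective is built on the model's prediction function (not on the
    linear algebra of the design matrix), with a numerically estimated
    Jacobian — the generic nonlinear path.  Because the model is linear
    in its parameters it must converge to the closed-form solution from
    any finite ``init`` (default: all zeros).

    Raises :class:`ConvergenceError` (carrying the last iterate) when the
    optimizer stops without meeting the tolerances within ``max_iter``
    function evaluations.
    """
    X, y = _mean_rows(data)
    _check_rank(X)
    ga = data.ga[np.isfinite(data.mean)]
    pna = data.pna[np.isfinite(data.mean)]
    x0 = np.zeros(5) if init is None else init.as_array()

    def residuals(p):
        return evaluate_mean(SurfaceParameters.from_array(p), ga, pna) - y

    res = least_squares(residuals, x0, method="lm",
                        xtol=tol, gtol=tol, ftol=tol, max_nfev=max_iter)
    if not res.success:
        raise ConvergenceError(
            f"Levenberg-Marquardt did not converge within {max_iter} "
            f"function evaluations (status {res.status}: {res.message})",
            iterate=SurfaceParameters.from_array(res.x),
            n_iterations=int(res.nfev))
    sse, mae = _diagnostics(X, y, res.x)
    return FitResult(surface=SurfaceParameters.from_array(res.x),
                     sse=sse, mae_insample=mae, n_points=len(y),
                     converged=True, n_iterations=int(res.nfev),
                     method=FitMethod.LEVENBERG_MARQUARDT)


def estimate_offset(data: GridDataset,
                    surface: SurfaceParameters) -> float:
    """Least-squares constant band half-width from percentile columns.

    Pools every available half-spread (mean − p5) and (p95 − mean) and
    returns their mean.  Where the dataset's own mean is missing, the
    fitted mean from ``surface`` is used instead.  Raises
    :class:`MissingDataError` when no percentile value is present.
    """
    fitted = evaluate_mean(surface, data.ga, data.pna)
    center = np.where(np.isfinite(data.mean), data.mean, fitted)
    spreads = []
    lo = np.isfinite(data.p5)
    if np.any(lo):
        spreads.append(center[lo] - data.p5[lo])
    hi = np.isfinite(data.p95)
    if np.any(hi):
        spreads.append(data.p95[hi] - center[hi])
    if not spreads:
        raise MissingDataError(
            "no p5 or p95 values present; cannot estimate the offset")
    return float(np.mean(np.concatenate(spreads)))
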