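"""Tied bi-quadratic reference-range surfaces for neonatal cHb and Hct.

The mean reference value of an analyte (hemoglobin concentration cHb in
g/dL, or hematocrit Hct in %) is modelled as a polynomial surface in
gestational age at birth (GA, weeks) and postnatal age (PNA, days):

    mean(GA, PNA) = p1·(1 + PNA) + p2·GA + p3·GA² + p4·GA·PNA + p5·PNA²

Note the *tied* first coefficient: p1 serves simultaneously as the
intercept and as the linear-PNA coefficient, so the surface has exactly
five free parameters.  The 5th and 95th percentile surfaces are the mean
surface shifted down/up by a single constant offset (γ for cHb, λ for
Hct), i.e. the reference band has constant width 2·offset everywhere.

Shipped presets cover GA 22–42 weeks and PNA 0–28 days.  Queries outside
that domain are evaluated anyway (the surface is a global polynomial) but
flagged as extrapolated and a warning is emitted.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidInputError, UsageError

__all__ = [
    "Analyte",
    "SurfaceParameters",
    "ReferenceModel",
    "ReferenceBand",
    "Observation",
    "Flag",
    "ExtrapolationWarning",
    "CHB_SURFACE",
    "HCT_SURFACE",
    "CHB_OFFSET",
    "HCT_OFFSET",
    "DEFAULT_GA_DOMAIN",
    "DEFAULT_PNA_DOMAIN",
    "chb_reference_model",
    "hct_reference_model",
    "get_model",
    "evaluate_mean",
    "evaluate_band",
    "classify",
    "partial_derivatives",
]


class ExtrapolationWarning(UserWarning):
    """Query lies outside the model's fitted GA/PNA domain."""


class Analyte(str, enum.Enum):
    """Blood analyte the reference model describes."""

    CHB = "cHb"
    HCT = "Hct"

    @classmethod
    def parse(cls, name: "str | Analyte") -> "Analyte":
        """Case-insensitive lookup: 'chb', 'cHb', 'HCT' all resolve."""
        if isinstance(name, cls):
            return name
        key = str(name).strip().lower()
        for member in cls:
            if member.value.lower() == key:
                return member
        raise UsageError(f"unknown analyte {name!r}; expected one of "
                         f"{[m.value for m in cls]}")


#: canonical display unit per analyte
UNITS: dict[Analyte, str] = {Analyte.CHB: "g/dL", Analyte.HCT: "%"}


def _require_finite(**named) -> None:
    for name, value in named.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class SurfaceParameters:
    """The five coefficients of one tied bi-quadratic mean surface.

    ``p1`` doubles as intercept and linear-PNA coefficient; ``p2`` is per
    week, ``p3`` per week², ``p4`` per week·day, ``p5`` per day².
    """

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float

    def __post_init__(self):
        for name in ("p1", "p2", "p3", "p4", "p5"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise InvalidInputError(f"coefficient {name} must be a finite "
                                        f"real number, got {v!r}")
            object.__setattr__(self, name, float(v))

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4, self.p5])

    @classmethod
    def from_array(cls, values) -> "SurfaceParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (5,):
            raise InvalidInputError(
                f"expected exactly 5 coefficients, got shape {values.shape}")
        return cls(*values.tolist())


# Published coefficients (bit-exact as printed).
CHB_SURFACE = SurfaceParameters(-0.3409, 0.8300, -0.0093, 0.0003, 0.0058)
HCT_SURFACE = SurfaceParameters(-1.2956, 2.5369, -0.0300, 0.0069, 0.0190)

#: constant half-width of the 5th–95th percentile band, g/dL
CHB_OFFSET = 3.76
#: constant half-width of the 5th–95th percentile band, %
HCT_OFFSET = 10.69

DEFAULT_GA_DOMAIN = (22.0, 42.0)   # completed weeks
DEFAULT_PNA_DOMAIN = (0.0, 28.0)   # days of life


@dataclass(frozen=True)
class ReferenceModel:
    """A mean surface plus a constant percentile offset and its domain."""

    analyte: Analyte
    surface: SurfaceParameters
    offset: float
    unit: str = ""
    domain_ga: tuple[float, float] = DEFAULT_GA_DOMAIN
    domain_pna: tuple[float, float] = DEFAULT_PNA_DOMAIN
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "analyte", Analyte.parse(self.analyte))
        if not self.unit:
            object.__setattr__(self, "unit", UNITS[self.analyte])
        _require_finite(offset=self.offset)
        if self.offset < 0:
            raise InvalidInputError(
                f"percentile offset must be nonnegative, got {self.offset}")
        for name in ("domain_ga", "domain_pna"):
            lo, hi = getattr(self, name)
            _require_finite(**{name: (lo, hi)})
            if lo > hi:
                raise InvalidInputError(f"{name} interval is empty: "
                                        f"[{lo}, {hi}]")
            object.__setattr__(self, name, (float(lo), float(hi)))
        object.__setattr__(self, "offset", float(self.offset))

    def in_domain(self, ga, pna):
        """True where (ga, pna) lies inside the closed validity box."""
        ga = np.asarray(ga, dtype=float)
        pna = np.asarray(pna, dtype=float)
        ok = ((self.domain_ga[0] <= ga) & (ga <= self.domain_ga[1])
              & (self.domain_pna[0] <= pna) & (pna <= self.domain_pna[1]))
        return bool(ok) if ok.ndim == 0 else ok

    def with_offset(self, offset: float) -> "ReferenceModel":
        return replace(self, offset=offset)


def chb_reference_model() -> ReferenceModel:
    """The shipped hemoglobin-concentration model (g/dL)."""
    return ReferenceModel(
        analyte=Analyte.CHB, surface=CHB_SURFACE, offset=CHB_OFFSET,
        provenance="published tied bi-quadratic fit, GA 22-42 wk, PNA 0-28 d")


def hct_reference_model() -> ReferenceModel:
    """The shipped hematocrit model (%)."""
    return ReferenceModel(
        analyte=Analyte.HCT, surface=HCT_SURFACE, offset=HCT_OFFSET,
        provenance="published tied bi-quadratic fit, GA 22-42 wk, PNA 0-28 d")


def get_model(analyte: "str | Analyte") -> ReferenceModel:
    """Shipped preset for the given analyte (case-insensitive name)."""
    analyte = Analyte.parse(analyte)
    return chb_reference_model() if analyte is Analyte.CHB \
        else hct_reference_model()


def evaluate_mean(surface: SurfaceParameters, ga, pna):
    """Mean reference value at (ga weeks, pna days).

    Vectorized: scalar inputs give a float, array inputs broadcast.
    Raises :class:`InvalidInputError` on non-finite input.
    """
    _require_finite(ga=ga, pna=pna)
    ga = np.asarray(ga, dtype=float)
    pna = np.asarray(pna, dtype=float)
    out = (surface.p1 * (1.0 + pna) + surface.p2 * ga
           + surface.p3 * ga ** 2 + surface.p4 * ga * pna
           + surface.p5 * pna ** 2)
    return float(out) if out.ndim == 0 else out


def partial_derivatives(surface: SurfaceParameters, ga, pna):
    """Gradient of the mean surface: (d/dGA, d/dPNA).

    d/dGA  = p2 + 2·p3·GA + p4·PNA
    d/dPNA = p1 + p4·GA + 2·p5·PNA   (the tied p1 reappears here)
    """
    _require_finite(ga=ga, pna=pna)
    ga = np.asarray(ga, dtype=float)
    pna = np.asarray(pna, dtype=float)
    d_ga = surface.p2 + 2.0 * surface.p3 * ga + surface.p4 * pna
    d_pna = surface.p1 + surface.p4 * ga + 2.0 * surface.p5 * pna
    if d_ga.ndim == 0:
        return float(d_ga), float(d_pna)
    return d_ga, d_pna


@dataclass(frozen=True)
class ReferenceBand:
    """Mean and 5th/95th percentile reference values at one (GA, PNA)."""

    mean: float
    p5: float
    p95: float
    extrapolated: bool = False

    def __post_init__(self):
        if not (self.p5 <= self.mean <= self.p95):
            raise InvalidInputError(
                f"band out of order: p5={self.p5}, mean={self.mean}, "
                f"p95={self.p95}")


def evaluate_band(model: ReferenceModel, ga: float, pna: float,
                  warn: bool = True) -> ReferenceBand:
    """Reference band at one (ga, pna); extrapolated queries still evaluate.

    Outside the validity domain the band is returned with
    ``extrapolated=True`` and (by default) an :class:`ExtrapolationWarning`.
    """
    mean = evaluate_mean(model.surface, ga, pna)
    extrapolated = not model.in_domain(ga, pna)
    if extrapolated and warn:
        warnings.warn(
            f"query (GA={ga} wk, PNA={pna} d) is outside the "
            f"{model.analyte.value} model domain GA {model.domain_ga}, "
            f"PNA {model.domain_pna}; result is an extrapolation",
            ExtrapolationWarning, stacklevel=2)
    return ReferenceBand(mean=mean, p5=mean - model.offset,
                         p95=mean + model.offset, extrapolated=extrapolated)


class Flag(str, enum.Enum):
    """Position of a measured value relative to the reference band."""

    BELOW = "below"
    WITHIN = "within"
    ABOVE = "above"


@dataclass(frozen=True)
class Observation:
    """One measured analyte value on one neonate."""

    id: str
    ga: float
    pna: float
    analyte: Analyte
    value: float
    post_transfusion: bool = False

    def __post_init__(self):
        object.__setattr__(self, "analyte", Analyte.parse(self.analyte))
        _require_finite(ga=self.ga, pna=self.pna, value=self.value)
        if self.ga <= 0:
            raise InvalidInputError(f"ga must be > 0, got {self.ga}")
        if self.pna < 0:
            raise InvalidInputError(f"pna must be >= 0, got {self.pna}")
        if self.value <= 0:
            raise InvalidInputError(f"value must be > 0, got {self.value}")
        for name in ("ga", "pna", "value"):
            object.__setattr__(self, name, float(getattr(self, name)))


def classify(model: ReferenceModel, obs: Observation,
             warn: bool = True) -> tuple[Flag, ReferenceBand]:
    """Flag an observation against the model's 5th–95th percentile band.

    Boundary values are inclusive: a value exactly equal to p5 or p95 is
    ``within``.  Raises :class:`UsageError` on analyte mismatch.
    """
    if obs.analyte is not model.analyte:
        raise UsageError(
            f"observation analyte {obs.analyte.value} does not match model "
            f"analyte {model.analyte.value}")
    band = evaluate_band(model, obs.ga, obs.pna, warn=warn)
    if obs.value < band.p5:
        flag = Flag.BELOW
    elif obs.value > band.p95:
        flag = Flag.ABOVE
    else:
        flag = Flag.WITHIN
    return flag, band
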