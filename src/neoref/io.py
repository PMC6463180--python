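"""Readers/writers for models (JSON), grids and cohorts (CSV).

File dialects
-------------
* model JSON: ``{analyte, unit, parameters[5], offset, domain_ga[2],
  domain_pna[2], provenance}`` — shipped presets ``chb_table1.json``
  and ``hct_table1.json`` live under :mod:`neoref.presets`;
* grid CSV: header ``ga_weeks,pna_days,mean,p5,p95`` (p5/p95 cells may
  be empty), "." decimal, UTF-8;
* cohort CSV: header ``id,ga_weeks,pna_days,analyte,value`` with an
  optional ``post_transfusion`` column.

Rows violating observation invariants are rejected individually with
line-numbered messages; accepted/rejected counts are logged.  Floats are
serialized at repr precision so round-trips are bit-exact.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (FormatError, InvalidInputError, MissingDataError,
                         NeorefError)
from .fitting import GRID_COLUMNS, GridDataset
from .model import (Analyte, Observation, ReferenceModel, SurfaceParameters,
                    evaluate_band)

logger = logging.getLogger(__name__)

__all__ = ["load_model", "save_model", "load_preset",
           "read_grid_csv", "write_grid_csv",
           "read_cohort_csv", "write_cohort_csv",
           "export_reference_table"]

_MODEL_FIELDS = {"analyte", "unit", "parameters", "offset",
                 "domain_ga", "domain_pna"}

COHORT_COLUMNS = ("id", "ga_weeks", "pna_days", "analyte", "value")


def _model_to_dict(model: ReferenceModel) -> dict:
    return {
        "analyte": model.analyte.value,
        "unit": model.unit,
        "parameters": list(model.surface.as_array()),
        "offset": model.offset,
        "domain_ga": list(model.domain_ga),
        "domain_pna": list(model.domain_pna),
        "provenance": model.provenance,
    }


def _model_from_dict(doc: dict, source: str = "<dict>") -> ReferenceModel:
    if not isinstance(doc, dict):
        raise FormatError(f"{source}: model document must be a JSON object")
    missing = _MODEL_FIELDS - doc.keys()
    if missing:
        raise FormatError(f"{source}: missing field(s) {sorted(missing)}")
    params = doc["parameters"]
    if not isinstance(params, list) or len(params) != 5:
        raise FormatError(f"{source}: field 'parameters' must hold exactly "
                          f"5 coefficients, got {params!r}")
    for name in ("domain_ga", "domain_pna"):
        if not isinstance(doc[name], list) or len(doc[name]) != 2:
            raise FormatError(f"{source}: field '{name}' must be a "
                              f"2-element interval")
    try:
        return ReferenceModel(
            analyte=Analyte.parse(doc["analyte"]),
            unit=str(doc["unit"]),
            surface=SurfaceParameters.from_array(params),
            offset=float(doc["offset"]),
            domain_ga=tuple(doc["domain_ga"]),
            domain_pna=tuple(doc["domain_pna"]),
            provenance=str(doc.get("provenance", "")))
    except InvalidInputError as exc:
        raise FormatError(f"{source}: {exc}") from exc


def save_model(model: ReferenceModel, path) -> None:
    Path(path).write_text(json.dumps(_model_to_dict(model), indent=2) + "\n",
                          encoding="utf-8")


def load_model(path) -> ReferenceModel:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    return _model_from_dict(doc, source=str(path))


def load_preset(analyte: "str | Analyte") -> ReferenceModel:
    """Load a shipped preset model (``chb_table1.json``/``hct_table1.json``)."""
    analyte = Analyte.parse(analyte)
    name = "chb_table1.json" if analyte is Analyte.CHB else "hct_table1.json"
    doc = json.loads(resources.files("neoref.presets")
                     .joinpath(name).read_text(encoding="utf-8"))
    return _model_from_dict(doc, source=f"preset {name}")


def _require_columns(frame: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; "
                          f"found {list(frame.columns)}")


def read_grid_csv(path, analyte: "str | Analyte" = Analyte.CHB
                  ) -> GridDataset:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise MissingDataError(f"{path}: file is empty") from exc
    _require_columns(frame, ("ga_weeks", "pna_days", "mean"), path)
    if len(frame) == 0:
        raise MissingDataError(f"{path}: no data rows")
    for optional in ("p5", "p95"):
        if optional not in frame.columns:
            frame[optional] = np.nan
    return GridDataset.from_frame(frame, analyte=analyte)


def write_grid_csv(data: GridDataset, path) -> None:
    data.to_frame().to_csv(path, index=False, columns=list(GRID_COLUMNS))


def read_cohort_csv(path) -> list[Observation]:
    """Typed observations; invalid rows are rejected with line numbers."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise MissingDataError(f"{path}: file is empty") from exc
    _require_columns(frame, COHORT_COLUMNS, path)
    if len(frame) == 0:
        raise MissingDataError(f"{path}: no data rows")
    observations, rejected = [], []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        try:
            observations.append(Observation(
                id=str(row["id"]),
                ga=float(row["ga_weeks"]),
                pna=float(row["pna_days"]),
                analyte=Analyte.parse(row["analyte"]),
                value=float(row["value"]),
                post_transfusion=bool(row.get("post_transfusion", False))))
        except (NeorefError, ValueError, TypeError) as exc:
            rejected.append((line, str(exc)))
    for line, msg in rejected:
        logger.warning("%s line %d: rejected (%s)", path, line, msg)
    logger.info("%s: accepted %d row(s), rejected %d",
                path, len(observations), len(rejected))
    return observations


def write_cohort_csv(cohort: list[Observation], path) -> None:
    pd.DataFrame({
        "id": [o.id for o in cohort],
        "ga_weeks": [o.ga for o in cohort],
        "pna_days": [o.pna for o in cohort],
        "analyte": [o.analyte.value for o in cohort],
        "value": [o.value for o in cohort],
        "post_transfusion": [o.post_transfusion for o in cohort],
    }).to_csv(path, index=False)


def export_reference_table(model: ReferenceModel, ga_list, pna_list,
                           path=None, round_to: int | None = None
                           ) -> pd.DataFrame:
    """Cartesian reference table of (ga, pna, mean, p5, p95, extrapolated).

    ``round_to`` affects only the written file (clinical display); the
    returned frame keeps full precision.
    """
    ga_list = list(ga_list)
    pna_list = list(pna_list)
    if not ga_list or not pna_list:
        raise MissingDataError("ga_list and pna_list must be nonempty")
    rows = []
    for ga in ga_list:
        for pna in pna_list:
            band = evaluate_band(model, ga, pna, warn=False)
            rows.append((ga, pna, band.mean, band.p5, band.p95,
                         band.extrapolated))
    frame = pd.DataFrame(rows, columns=["ga_weeks", "pna_days", "mean",
                                        "p5", "p95", "extrapolated"])
    if path is not None:
        out = frame.copy()
        if round_to is not None:
            for col in ("mean", "p5", "p95"):
                out[col] = out[col].round(round_to)
        try:
            out.to_csv(path, index=False)
        except OSError as exc:
            raise NeorefError(f"could not write {path}: {exc}") from exc
    return frame
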