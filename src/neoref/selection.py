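"""Accuracy–complexity model selection over a quadratic term library.

The functional form of the reference surface was originally discovered
by symbolic regression; here the search is made reproducible as an
exhaustive scan of coefficient subsets drawn from a fixed library of
seven polynomial terms in GA and PNA:

    1, PNA, (1+PNA) tied, GA, GA², GA·PNA, PNA²

The tied term (one coefficient multiplying both the constant and the
linear-PNA basis) is mutually exclusive with the separate intercept and
linear-PNA terms.  Every admissible subset is fitted by closed-form
least squares and the non-dominated set in (number of parameters,
squared error) — the accuracy–complexity Pareto front — is reported.
The shipped 5-parameter tied bi-quadratic is the front member this
search is designed to exhibit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import MissingDataError
from .fitting import GridDataset

logger = logging.getLogger(__name__)

__all__ = [
    "TERM_LIBRARY",
    "CandidateModel",
    "admissible_masks",
    "enumerate_candidates",
    "pareto_front",
    "candidate_table",
]

#: term name -> column builder, in canonical (lexicographic tie-break) order
TERM_LIBRARY = {
    "1": lambda ga, pna: np.ones_like(ga),
    "PNA": lambda ga, pna: pna,
    "1+PNA": lambda ga, pna: 1.0 + pna,
    "GA": lambda ga, pna: ga,
    "GA^2": lambda ga, pna: ga ** 2,
    "GA*PNA": lambda ga, pna: ga * pna,
    "PNA^2": lambda ga, pna: pna ** 2,
}

_ORDER = {name: i for i, name in enumerate(TERM_LIBRARY)}


@dataclass(frozen=True)
class CandidateModel:
    """One fitted term subset with its accuracy and complexity."""

    terms: tuple[str, ...]
    n_params: int
    sse: float
    mae: float
    coefficients: tuple[float, ...]

    @property
    def mask(self) -> str:
        return "+".join(self.terms)


def admissible_masks(max_params: int = 7) -> list[tuple[str, ...]]:
    """All nonempty term subsets with at most ``max_params`` coefficients.

    Subsets containing the tied '1+PNA' term must not also contain the
    separate '1' or 'PNA' terms (they encode the same basis directions).
    """
    names = list(TERM_LIBRARY)
    masks = []
    for r in range(1, min(max_params, len(names)) + 1):
        for combo in itertools.combinations(names, r):
            if "1+PNA" in combo and ("1" in combo or "PNA" in combo):
                continue
            masks.append(tuple(sorted(combo, key=_ORDER.__getitem__)))
    return masks


def _candidate_design(terms: tuple[str, ...], ga: np.ndarray,
                      pna: np.ndarray) -> np.ndarray:
    return np.column_stack([TERM_LIBRARY[t](ga, pna) for t in terms])


def enumerate_candidates(data: GridDataset,
                         max_params: int = 7) -> list[CandidateModel]:
    """Fit every admissible term subset by closed-form least squares.

    Rank-deficient candidates (e.g. the GA·PNA term on a PNA=0 slice)
    are skipped with a log entry.  Raises :class:`MissingDataError` on an
    empty dataset.
    """
    keep = np.isfinite(data.mean)
    if len(data) == 0 or not np.any(keep):
        raise MissingDataError("no mean values to select a model on")
    ga, pna, y = data.ga[keep], data.pna[keep], data.mean[keep]
    candidates = []
    for terms in admissible_masks(max_params):
        X = _candidate_design(terms, ga, pna)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            logger.info("skipping rank-deficient candidate %s",
                        "+".join(terms))
            continue
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        candidates.append(CandidateModel(
            terms=terms, n_params=len(terms),
            sse=float(resid @ resid), mae=float(np.mean(np.abs(resid))),
            coefficients=tuple(coef.tolist())))
    return candidates


def _mask_key(c: CandidateModel) -> tuple[int, ...]:
    return tuple(_ORDER[t] for t in c.terms)


def pareto_front(candidates: list[CandidateModel]) -> list[CandidateModel]:
    """Candidates not dominated in (n_params decreasing-better, sse).

    Sorted by n_params ascending; exact ties on both axes keep the
    lexicographically smallest term mask.
    """
    if not candidates:
        raise MissingDataError("no candidates to build a Pareto front from")
    front = []
    for c in candidates:
        dominated = any(
            (o.n_params <= c.n_params and o.sse <= c.sse
             and (o.n_params < c.n_params or o.sse < c.sse))
            for o in candidates)
        if dominated:
            continue
        twin = next((f for f in front if f.n_params == c.n_params
                     and f.sse == c.sse), None)
        if twin is None:
            front.append(c)
        elif _mask_key(c) < _mask_key(twin):
            front[front.index(twin)] = c
    front.sort(key=lambda c: (c.n_params, c.sse, _mask_key(c)))
    return front


def candidate_table(candidates: list[CandidateModel],
                    front: list[CandidateModel] | None = None
                    ) -> pd.DataFrame:
    """Export table: mask, n_params, sse, mae, on_front."""
    if front is None:
        front = pareto_front(candidates)
    front_masks = {c.mask for c in front}
    return pd.DataFrame({
        "mask": [c.mask for c in candidates],
        "n_params": [c.n_params for c in candidates],
        "sse": [c.sse for c in candidates],
        "mae": [c.mae for c in candidates],
        "on_front": [c.mask in front_masks for c in candidates],
    })
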