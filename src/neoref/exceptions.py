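"""Exception hierarchy.

Every error raised by :mod:`neoref` derives from :class:`NeorefError`, so
callers (and the CLI) can map failures onto stable categories.
"""

from __future__ import annotations


class NeorefError(Exception):
    """Base class for all neoref errors."""

    category = "error"


class InvalidInputError(NeorefError, ValueError):
    """Non-finite or otherwise physically impossible numeric input."""

    category = "invalid-input"


class UsageError(NeorefError, ValueError):
    """API misuse, e.g. classifying a Hct value against the cHb model."""

    category = "usage"


class FormatError(NeorefError, ValueError):
    """Malformed file: wrong schema, missing column, bad arity."""

    category = "format"


class MissingDataError(NeorefError, ValueError):
    """An operation needs data the input does not contain."""

    category = "missing-data"


class IdentifiabilityError(NeorefError, ValueError):
    """Rank-deficient design: some coefficient directions are not estimable.

    ``directions`` names the offending basis-term combinations.
    """

    category = "identifiability"

    def __init__(self, message: str, directions: list[str] | None = None):
        super().__init__(message)
        self.directions = directions or []


class ConvergenceError(NeorefError, RuntimeError):
    """Iterative fit did not converge; carries the last iterate."""

    category = "convergence"

    def __init__(self, message: str, iterate=None, n_iterations: int = 0):
        super().__init__(message)
        self.iterate = iterate
        self.n_iterations = n_iterations
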