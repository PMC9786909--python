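"""Shared helpers: error types and display rounding."""

from __future__ import annotations

import math


class StepsenseError(Exception):
    """Base class for all package errors."""


class FormatError(StepsenseError):
    """A file does not follow the documented dialect."""


class DataError(StepsenseError):
    """Structurally valid input with inconsistent content."""


class EmptyInputError(StepsenseError):
    """An operation received an empty input it cannot act on."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (display convention for biases/percentages).

    Python's built-in ``round`` uses banker's rounding; reported biases are
    rounded half-up instead, e.g. 912.5 -> 913, -912.5 -> -913.
    """
    factor = 10.0**ndigits
    scaled = x * factor
    rounded = math.floor(scaled + 0.5) if scaled >= 0 else math.ceil(scaled - 0.5)
    out = rounded / factor
    return int(out) if ndigits <= 0 else out
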