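"""Shared primitives: scan-status vocabulary, error types, rounding helpers."""

from __future__ import annotations

import enum
import math
from decimal import Decimal, ROUND_HALF_UP
from typing import Any


class AmyloidStatus(str, enum.Enum):
    """Binary amyloid scan status, with an explicit indeterminate state.

    ``indeterminate`` arises only from missing inputs or declared ties
    (e.g. an even reader panel split); it is never produced by the
    classification rule itself.
    """

    POSITIVE = "positive"
    NEGATIVE = "negative"
    INDETERMINATE = "indeterminate"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


class SchemaError(ValueError):
    """Input table or mapping violates the declared schema (labels, scores)."""


class InvalidInputError(ValueError):
    """Input values are structurally valid but unusable (e.g. one-class truth)."""


def is_missing(value: Any) -> bool:
    """True for None, NaN, or the string sentinels 'NA'/''. """
    if value is None:
        return True
    if isinstance(value, str):
        return value.strip() in {"", "NA", "NaN", "nan"}
    try:
        return math.isnan(float(value))
    except (TypeError, ValueError):
        return False


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, the convention used in report tables.

    Python's built-in ``round`` is banker's rounding (92.5 -> 92); report
    percentages are conventionally rounded half-up (92.5 -> 93).
    """
    if is_missing(value):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    out = float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
    return out


def as_status(value: Any) -> AmyloidStatus:
    """Coerce common encodings to :class:`AmyloidStatus`.

    Accepts AmyloidStatus, the strings positive/negative/indeterminate
    (case-insensitive), pathology present/absent, booleans and 0/1.
    Missing values map to indeterminate.
    """
    if isinstance(value, AmyloidStatus):
        return value
    if is_missing(value):
        return AmyloidStatus.INDETERMINATE
    if isinstance(value, str):
        key = value.strip().lower()
        mapping = {
            "positive": AmyloidStatus.POSITIVE,
            "negative": AmyloidStatus.NEGATIVE,
            "indeterminate": AmyloidStatus.INDETERMINATE,
            "present": AmyloidStatus.POSITIVE,
            "absent": AmyloidStatus.NEGATIVE,
        }
        if key in mapping:
            return mapping[key]
        raise SchemaError(f"unrecognized status label: {value!r}")
    if isinstance(value, bool) or value in (0, 1):
        return AmyloidStatus.POSITIVE if value else AmyloidStatus.NEGATIVE
    raise SchemaError(f"cannot interpret {value!r} as a scan status")
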