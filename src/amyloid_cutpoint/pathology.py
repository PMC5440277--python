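"""Histopathological amyloid determination from dual-stain categorical scores.

Each considered brain region (frontal cortex and posterior cingulate cortex —
the two regions that are both stained and visually assessed) carries a
neuritic-plaque density score from two stains: Bielschowsky silver stain
(BSS) and immunohistochemistry (IHC), each graded none / sparse / moderate /
frequent.  Neuritic amyloid is *present* in a region when either stain is
moderate or frequent, *absent* when every available stain is none or sparse.
A single missing stain does not block classification; both missing gives an
indeterminate region.

Subject-level positivity defaults to the any-positive-region rule (one
present region suffices); an all-regions rule is available via ``rule``.
"""

from __future__ import annotations

from collections.abc import Iterable

import pandas as pd

from .core import AmyloidStatus, InvalidInputError, SchemaError, is_missing

PLAQUE_SCORES: tuple[str, ...] = ("none", "sparse", "moderate", "frequent")
_LOADED = {"moderate", "frequent"}

PRESENT = "present"
ABSENT = "absent"
INDETERMINATE = "indeterminate"


def _check_stain(score, stain: str) -> str | None:
    if is_missing(score):
        return None
    s = str(score).strip().lower()
    if s not in PLAQUE_SCORES:
        raise SchemaError(f"{stain} score must be one of {PLAQUE_SCORES}, got {score!r}")
    return s


def classify_region(bss, ihc) -> str:
    """Present if any available stain is moderate/frequent; absent if all
    available stains are none/sparse; indeterminate if both are missing."""
    b = _check_stain(bss, "BSS")
    i = _check_stain(ihc, "IHC")
    available = [s for s in (b, i) if s is not None]
    if not available:
        return INDETERMINATE
    return PRESENT if any(s in _LOADED for s in available) else ABSENT


def classify_subject(regional_statuses: Iterable[str], rule: str = "any") -> AmyloidStatus:
    """Aggregate per-region present/absent calls to a subject-level status.

    rule="any": positive if any determinate region is present (default).
    rule="all": positive only if every determinate region is present.
    All regions indeterminate -> indeterminate; no regions -> error.
    """
    statuses = list(regional_statuses)
    if not statuses:
        raise InvalidInputError("classify_subject requires at least one regional record")
    determinate = [s for s in statuses if s in (PRESENT, ABSENT)]
    if not determinate:
        return AmyloidStatus.INDETERMINATE
    if rule == "any":
        positive = any(s == PRESENT for s in determinate)
    elif rule == "all":
        positive = all(s == PRESENT for s in determinate)
    else:
        raise SchemaError(f"rule must be 'any' or 'all', got {rule!r}")
    return AmyloidStatus.POSITIVE if positive else AmyloidStatus.NEGATIVE


def subject_status_table(pathology: pd.DataFrame, rule: str = "any") -> pd.DataFrame:
    """Subject-level amyloid status from a long regional pathology table.

    ``pathology`` has columns ``subject_id, region, bss, ihc`` (a precomputed
    ``status`` column is honoured if present instead of the stains).
    Returns ``subject_id, status``.
    """
    required = {"subject_id", "region"}
    if not required.issubset(pathology.columns):
        raise SchemaError(f"pathology table needs columns {sorted(required)}")
    rows = []
    for subject_id, sub in pathology.groupby("subject_id", sort=True):
        if "status" in sub.columns and sub["status"].notna().all():
            regional = [str(s).strip().lower() for s in sub["status"]]
        else:
            regional = [classify_region(b, i) for b, i in zip(sub["bss"], sub["ihc"])]
        rows.append(
            {"subject_id": subject_id, "status": classify_subject(regional, rule=rule).value}
        )
    return pd.DataFrame(rows)
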