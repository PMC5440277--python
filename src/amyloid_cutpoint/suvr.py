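"""SUVR quantification: reference activities, ratios, composites, classification.

The standardized uptake value ratio (SUVR) of a cortical target region is its
mean tracer activity divided by the activity of a reference region assumed to
be amyloid-free.  The composite SUVR is the unweighted arithmetic mean of six
cortical regional SUVRs.  A scan is called amyloid-positive when its SUVR
meets or exceeds a positivity cutoff (``suvr >= cutoff``); comparisons happen
at the precision the values were supplied in, with no internal re-rounding.

Missing inputs propagate as NaN ("missing") rather than raising, so one bad
subject never halts a batch; structurally invalid inputs (non-positive
reference activity, a wrong region set) do raise.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .core import AmyloidStatus, InvalidInputError, SchemaError, is_missing
from .regions import (
    COMPOSITE_REGIONS,
    REFERENCE_REGIONS,
    REFERENCE_SOURCE,
)


def whole_cerebellum_activity(gcer_activity: float, cwm_activity: float) -> float:
    """Mean of cerebellar gray- and white-matter activities (unweighted).

    Returns NaN if either input is missing or non-positive, so downstream
    SUVRs for the whole-cerebellum reference come out missing instead of
    aborting the batch.
    """
    if is_missing(gcer_activity) or is_missing(cwm_activity):
        return math.nan
    g, w = float(gcer_activity), float(cwm_activity)
    if g <= 0 or w <= 0 or not (math.isfinite(g) and math.isfinite(w)):
        return math.nan
    return (g + w) / 2.0


def compute_suvr(
    cortical_activity: float,
    reference_activity: float,
    *,
    subject_id: str | None = None,
    region: str | None = None,
) -> float:
    """SUVR = target activity / reference activity.

    Missing inputs yield NaN.  A non-positive reference activity is a data
    error and raises, naming the subject and region when provided.
    """
    if is_missing(cortical_activity) or is_missing(reference_activity):
        return math.nan
    c, r = float(cortical_activity), float(reference_activity)
    where = f" (subject={subject_id!r}, region={region!r})" if subject_id or region else ""
    if not math.isfinite(r) or r <= 0:
        raise InvalidInputError(f"non-positive reference activity {r!r}{where}")
    if not math.isfinite(c) or c <= 0:
        raise InvalidInputError(f"non-positive target activity {c!r}{where}")
    return c / r


def compute_composite(regional_suvrs: Mapping[str, float]) -> float:
    """Arithmetic mean of the six cortical regional SUVRs.

    The mapping must cover exactly the six composite regions; a wrong region
    set raises a :class:`SchemaError` listing what is missing or extra.  Any
    missing (NaN) value makes the composite missing.
    """
    provided = set(regional_suvrs)
    expected = set(COMPOSITE_REGIONS)
    if provided != expected:
        missing = sorted(expected - provided)
        extra = sorted(provided - expected)
        raise SchemaError(
            f"composite requires exactly {sorted(expected)}; "
            f"missing={missing}, extra={extra}"
        )
    values = [regional_suvrs[r] for r in COMPOSITE_REGIONS]
    if any(is_missing(v) for v in values):
        return math.nan
    return float(np.mean([float(v) for v in values]))


def classify_scan(suvr: float, cutoff: float) -> AmyloidStatus:
    """Positive iff ``suvr >= cutoff``; missing SUVR -> indeterminate."""
    if is_missing(suvr):
        return AmyloidStatus.INDETERMINATE
    if is_missing(cutoff) or float(cutoff) <= 0:
        raise InvalidInputError(f"invalid cutoff {cutoff!r}")
    return AmyloidStatus.POSITIVE if float(suvr) >= float(cutoff) else AmyloidStatus.NEGATIVE


def suvr_table_from_activities(activity: pd.DataFrame) -> pd.DataFrame:
    """Derive the long SUVR table from a long regional-activity table.

    Parameters
    ----------
    activity
        Columns ``subject_id, region, activity`` with regions drawn from the
        closed activity vocabulary.

    Returns
    -------
    DataFrame with columns ``subject_id, reference_region, target_region,
    suvr, source`` covering the six cortical regions plus the composite for
    each of the four reference regions.  ``source`` records that these SUVRs
    were derived from activities (the alternative path is precomputed SUVRs
    loaded directly).
    """
    required = {"subject_id", "region", "activity"}
    if not required.issubset(activity.columns):
        raise SchemaError(f"activity table needs columns {sorted(required)}")
    rows: list[dict] = []
    for subject_id, sub in activity.groupby("subject_id", sort=True):
        act = dict(zip(sub["region"], sub["activity"]))
        refs = {rr: act.get(src, math.nan) for rr, src in REFERENCE_SOURCE.items()}
        refs["WCER"] = whole_cerebellum_activity(
            act.get("cerebellar_gray", math.nan), act.get("cerebellar_white", math.nan)
        )
        for rr in REFERENCE_REGIONS:
            ref_act = refs[rr]
            regional: dict[str, float] = {}
            for region in COMPOSITE_REGIONS:
                target_act = act.get(region, math.nan)
                if is_missing(ref_act) or is_missing(target_act):
                    value = math.nan
                else:
                    value = compute_suvr(
                        target_act, ref_act, subject_id=str(subject_id), region=region
                    )
                regional[region] = value
                rows.append(
                    {
                        "subject_id": subject_id,
                        "reference_region": rr,
                        "target_region": region,
                        "suvr": value,
                        "source": "activity",
                    }
                )
            rows.append(
                {
                    "subject_id": subject_id,
                    "reference_region": rr,
                    "target_region": "composite",
                    "suvr": compute_composite(regional),
                    "source": "activity",
                }
            )
    return pd.DataFrame(rows)


def classify_table(suvr: pd.DataFrame, cutoffs: pd.DataFrame) -> pd.DataFrame:
    """Classify every SUVR row against its (target, reference) cutoff.

    ``suvr`` is the long table (``subject_id, reference_region,
    target_region, suvr``); ``cutoffs`` has ``target_region,
    reference_region, cutoff``.  Rows without a matching cutoff are dropped;
    rows with missing SUVR come out indeterminate.  Output is sorted by
    (target_region, reference_region, subject_id) for deterministic diffs.
    """
    merged = suvr.merge(
        cutoffs[["target_region", "reference_region", "cutoff"]],
        on=["target_region", "reference_region"],
        how="inner",
    )
    merged["status"] = [
        classify_scan(s, c).value for s, c in zip(merged["suvr"], merged["cutoff"])
    ]
    cols = ["subject_id", "reference_region", "target_region", "suvr", "cutoff", "status"]
    return (
        merged[cols]
        .sort_values(["target_region", "reference_region", "subject_id"])
        .reset_index(drop=True)
    )
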