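"""Two-stage study orchestration: cutoff generation, then validation.

``run_generate`` reproduces the cutoff-generation stage (ROC/Youden against
the visual standard of truth on a mixed clinical cohort); ``run_validate``
applies a cutoff table to a validation cohort and reports performance against
histopathology and agreement with the visual majority read, per-subject error
listings, and Holm-corrected pairwise accuracy comparisons.  The report
functions only format numbers produced by the other modules — no arithmetic
happens here beyond rounding for display.

All output tables are sorted on stable keys so repeated runs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .core import AmyloidStatus, InvalidInputError, as_status, round_half_up
from .cutpoint import generate_cutoff_table
from .metrics import (
    ProportionEstimate,
    accuracy,
    confusion,
    pairwise_comparisons,
    percent_agreement,
    sensitivity,
    specificity,
)
from .regions import REFERENCE_REGIONS
from .suvr import classify_table
from .visual import per_reader_status, regional_majority, scan_majority

log = logging.getLogger(__name__)


def assessment_label(predicted, reference) -> str:
    """TP/TN/FP/FN label of one call against a reference; 'NA' if either is
    indeterminate."""
    p, r = as_status(predicted), as_status(reference)
    if AmyloidStatus.INDETERMINATE in (p, r):
        return "NA"
    if r is AmyloidStatus.POSITIVE:
        return "TP" if p is AmyloidStatus.POSITIVE else "FN"
    return "FP" if p is AmyloidStatus.POSITIVE else "TN"


def _pct(est: ProportionEstimate) -> tuple[float, float, float]:
    p, lo, hi = est.as_percent()
    return round_half_up(p), round_half_up(lo), round_half_up(hi)


def _manifest(stage: str, **info) -> dict:
    return {
        "stage": stage,
        "package_version": __version__,
        "decisions": {
            "positivity_rule": "suvr >= cutoff",
            "whole_cerebellum": "unweighted mean of cerebellar gray and white activity",
            "youden_tie_break": "highest specificity, then smallest threshold",
            "percent_rounding": "half-up to integers",
        },
        **info,
    }


def run_generate(
    suvr: pd.DataFrame,
    reads: pd.DataFrame | None = None,
    pathology_status: pd.DataFrame | None = None,
    sot_mode: str = "visual",
    candidates: str = "observed",
) -> dict:
    """Generate the cutoff table for every (target x reference region) pair.

    sot_mode="visual" derives scan-level truth from the readers' whole-brain
    classification (majority) and per-region truth from the regional uptake
    scores; sot_mode="histopathology" uses a subject-level pathology status
    table (composite target only, since pathology is not scored per SUVR
    target region).

    Returns ``{"cutoffs": DataFrame, "manifest": dict}``.
    """
    if sot_mode == "visual":
        if reads is None:
            raise InvalidInputError("visual standard of truth requires a reads table")
        scan_truth = scan_majority(reads)[["subject_id", "status"]]
        regional_truth = regional_majority(reads)[["subject_id", "region", "status"]]
    elif sot_mode == "histopathology":
        if pathology_status is None:
            raise InvalidInputError("histopathology standard of truth requires a status table")
        scan_truth = pathology_status[["subject_id", "status"]]
        regional_truth = None
    else:
        raise InvalidInputError(f"unknown sot_mode {sot_mode!r}")
    cutoffs = generate_cutoff_table(
        suvr, scan_truth, regional_truth, sot_mode=sot_mode, candidates=candidates
    )
    manifest = _manifest(
        "generate",
        sot_mode=sot_mode,
        candidates=candidates,
        n_subjects=int(suvr["subject_id"].nunique()),
        n_cutoffs=int(len(cutoffs)),
    )
    return {"cutoffs": cutoffs, "manifest": manifest}


def _composite_status_by_rr(classification: pd.DataFrame) -> dict[str, pd.DataFrame]:
    out = {}
    comp = classification[classification["target_region"] == "composite"]
    for rr in REFERENCE_REGIONS:
        block = comp[comp["reference_region"] == rr]
        if not block.empty:
            out[rr] = block[["subject_id", "status"]]
    return out


def run_validate(
    suvr: pd.DataFrame,
    cutoffs: pd.DataFrame,
    pathology_status: pd.DataFrame | None = None,
    va: pd.DataFrame | None = None,
    reads: pd.DataFrame | None = None,
    level: float = 0.95,
) -> dict:
    """Validate cutoff classification on a cohort.

    Parameters
    ----------
    suvr, cutoffs
        Long SUVR table and cutoff table (``target_region,
        reference_region, cutoff``).
    pathology_status
        Subject-level ``subject_id, status`` (present/absent) reference.
    va
        Subject-level visual majority ``subject_id, status``; derived from
        ``reads`` when omitted and reads are available.
    reads
        Per-reader scores; enables per-reader agreement rows.

    Returns a dict of DataFrames: ``classification``, ``validation``
    (performance vs pathology with exact CIs), ``agreement`` (pairwise
    percent agreement), ``errors`` (per-subject error listing), and
    ``comparisons`` (Holm-corrected pairwise accuracy chi-squared), plus a
    ``manifest``.
    """
    classification = classify_table(suvr, cutoffs)
    if va is None and reads is not None:
        va = scan_majority(reads)[["subject_id", "status"]]
    va_map = dict(zip(va["subject_id"], va["status"])) if va is not None else {}
    path_map = (
        dict(zip(pathology_status["subject_id"], pathology_status["status"]))
        if pathology_status is not None
        else {}
    )

    # -- performance vs histopathology, per (target, reference) -------------
    validation_rows = []
    if path_map:
        for (target, rr), block in classification.groupby(
            ["target_region", "reference_region"], sort=True
        ):
            ref = [path_map.get(s) for s in block["subject_id"]]
            cs = confusion(block["status"].tolist(), ref)
            row = {
                "target_region": target,
                "reference_region": rr,
                "tp": cs.tp,
                "fp": cs.fp,
                "tn": cs.tn,
                "fn": cs.fn,
                "excluded_missing": cs.excluded_missing,
            }
            for name, fn in (
                ("sensitivity", sensitivity),
                ("specificity", specificity),
                ("accuracy", accuracy),
            ):
                est = fn(cs, level)
                pct, lo, hi = _pct(est)
                row[name] = pct
                row[f"{name}_ci_low"] = lo
                row[f"{name}_ci_high"] = hi
                row[f"{name}_frac"] = est.point
            validation_rows.append(row)
    validation = pd.DataFrame(validation_rows)

    # -- pairwise percent agreement ----------------------------------------
    agreement_rows = []

    def add_agreement(comparison: str, rr: str | None, a, b):
        est = percent_agreement(a, b, level)
        pct, lo, hi = _pct(est)
        agreement_rows.append(
            {
                "comparison": comparison,
                "reference_region": rr if rr is not None else "-",
                "agree": est.numerator,
                "n": est.denominator,
                "percent": pct,
                "ci_low": lo,
                "ci_high": hi,
            }
        )

    by_rr = _composite_status_by_rr(classification)
    for rr, block in by_rr.items():
        if va_map:
            add_agreement(
                "suvr_vs_va", rr,
                block["status"].tolist(),
                [va_map.get(s) for s in block["subject_id"]],
            )
        if path_map:
            add_agreement(
                "suvr_vs_pathology", rr,
                block["status"].tolist(),
                [path_map.get(s) for s in block["subject_id"]],
            )
    if va_map and path_map:
        subjects = sorted(set(va_map) & set(path_map))
        add_agreement(
            "va_vs_pathology", None,
            [va_map[s] for s in subjects],
            [path_map[s] for s in subjects],
        )
    if reads is not None and path_map:
        for (reader_id, reader_class), sub in per_reader_status(reads).groupby(
            ["reader_id", "reader_class"], sort=True
        ):
            add_agreement(
                f"reader_{reader_id}_{reader_class}_vs_pathology", None,
                sub["status"].tolist(),
                [path_map.get(s) for s in sub["subject_id"]],
            )
    agreement = pd.DataFrame(agreement_rows)

    # -- per-subject error listing (composite analyses) ---------------------
    errors = pd.DataFrame()
    if path_map and by_rr:
        wide: dict[str, dict] = {}
        for rr, block in by_rr.items():
            for row in block.itertuples():
                ref = path_map.get(row.subject_id)
                entry = wide.setdefault(
                    row.subject_id,
                    {"subject_id": row.subject_id, "pathology": ref},
                )
                entry[f"assess_{rr.lower()}"] = assessment_label(row.status, ref)
        for sid, entry in wide.items():
            if sid in va_map:
                entry["va"] = va_map[sid]
                entry["assess_va"] = assessment_label(va_map[sid], entry["pathology"])
        listing = pd.DataFrame(list(wide.values()))
        assess_cols = [c for c in listing.columns if c.startswith("assess_")]
        mask = listing[assess_cols].isin(["FP", "FN"]).any(axis=1)
        errors = listing[mask].sort_values("subject_id").reset_index(drop=True)

    # -- pairwise chi-squared comparisons, Holm-corrected within each metric
    comparisons = pd.DataFrame()
    if path_map and by_rr:
        summaries: dict[str, object] = {}
        for rr, block in by_rr.items():
            summaries[rr] = confusion(
                block["status"].tolist(),
                [path_map.get(s) for s in block["subject_id"]],
            )
        if va_map:
            subjects = sorted(set(va_map) & set(path_map))
            summaries["VA"] = confusion(
                [va_map[s] for s in subjects], [path_map[s] for s in subjects]
            )
        rows = []
        for metric, num in (
            ("sensitivity", lambda c: (c.tp, c.tp + c.fn)),
            ("specificity", lambda c: (c.tn, c.tn + c.fp)),
            ("accuracy", lambda c: (c.tp + c.tn, c.n)),
        ):
            labels = list(summaries)
            counts = [num(summaries[lab]) for lab in labels]
            for c in pairwise_comparisons(
                labels, [x for x, _ in counts], [n for _, n in counts]
            ):
                rows.append(
                    {
                        "metric": metric,
                        "label_a": c.label_a,
                        "label_b": c.label_b,
                        "chi2": c.statistic,
                        "p_raw": c.p_raw,
                        "p_holm": c.p_adjusted,
                        "significant": c.significant,
                    }
                )
        comparisons = pd.DataFrame(rows)

    manifest = _manifest(
        "validate",
        n_subjects=int(suvr["subject_id"].nunique()),
        n_cutoffs=int(len(cutoffs)),
        has_pathology=bool(path_map),
        has_va=bool(va_map),
        has_reads=reads is not None,
    )
    return {
        "classification": classification,
        "validation": validation,
        "agreement": agreement,
        "errors": errors,
        "comparisons": comparisons,
        "manifest": manifest,
    }


def write_outputs(results: dict, out_dir: str | Path) -> list[Path]:
    """Write each DataFrame in ``results`` to CSV (and the manifest to JSON)
    with fixed formatting so reruns are byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            path = out / f"{name}.csv"
            obj.to_csv(path, index=False, float_format="%.6g")
        else:
            path = out / f"{name}.json"
            path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
        written.append(path)
        log.info("wrote %s", path)
    return written
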