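"""SUVR positivity-cutoff estimation by ROC analysis with Youden-index
maximization.

The estimation problem: given per-subject SUVR scores and a binary standard
of truth (visual read or histopathology), choose the threshold t such that
classifying ``score >= t`` as positive maximizes Youden's index
J = sensitivity + specificity - 1.  Candidate thresholds are the observed
score values plus a sentinel above the maximum (so the all-negative operating
point is available); a midpoint-candidate variant is provided as an option.
Ties in J are broken toward higher specificity, then the smallest threshold,
so output is deterministic.

The module exposes both the low-level operations (:func:`build_roc`,
:func:`youden_optimal`, :func:`auc`) and a model/results pair
(:class:`CutpointModel` / :class:`CutpointResults`) in the style of
statsmodels: build the model from data, call ``fit()``, inspect the results
object (``summary()``, ``classify()``, ``plot_roc()``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AmyloidStatus, InvalidInputError, as_status
from .regions import CUTOFF_TARGETS, REFERENCE_REGIONS, TARGET_TO_VISUAL


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve under the ``score >= threshold`` positivity rule.

    ``thresholds`` ascend; sensitivity is non-increasing and specificity
    non-decreasing along them.  The smallest observed score acts as the
    below-everything threshold (sens 1, spec 0) and the trailing +inf
    sentinel as the above-everything one (sens 0, spec 1).
    """

    thresholds: np.ndarray
    sens_at: np.ndarray
    spec_at: np.ndarray
    n_pos: int
    n_neg: int
    n_excluded: int = 0


@dataclass(frozen=True)
class CutoffResult:
    """A selected cutoff with its ROC provenance."""

    cutoff: float
    youden_j: float
    auc: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int
    target_region: str | None = None
    reference_region: str | None = None
    sot: str | None = None


def _coerce_binary_truth(
    scores: Sequence[float], truth: Sequence
) -> tuple[np.ndarray, np.ndarray, int]:
    s = np.asarray(scores, dtype=float)
    t = np.array([as_status(x) for x in truth], dtype=object)
    if s.shape != t.shape:
        raise InvalidInputError("scores and truth must be paired (same length)")
    keep = np.array(
        [st is not AmyloidStatus.INDETERMINATE for st in t]
    ) & np.isfinite(s)
    excluded = int((~keep).sum())
    s, t = s[keep], t[keep]
    y = np.array([st is AmyloidStatus.POSITIVE for st in t], dtype=bool)
    if y.sum() == 0:
        raise InvalidInputError("truth contains no positive labels")
    if (~y).sum() == 0:
        raise InvalidInputError("truth contains no negative labels")
    return s, y, excluded


def build_roc(scores: Sequence[float], truth: Sequence) -> RocCurve:
    """Empirical ROC from paired scores and binary truth labels.

    At each candidate threshold t (the sorted unique scores plus a +inf
    sentinel), sensitivity is the fraction of positives with score >= t and
    specificity the fraction of negatives with score < t.  Indeterminate
    truth or non-finite scores are excluded and counted.
    """
    s, y, excluded = _coerce_binary_truth(scores, truth)
    thresholds = np.append(np.unique(s), np.inf)
    pos, neg = s[y], s[~y]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return RocCurve(
        thresholds=thresholds,
        sens_at=sens,
        spec_at=spec,
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
        n_excluded=excluded,
    )


def midpoint_roc(scores: Sequence[float], truth: Sequence) -> RocCurve:
    """ROC with midpoints between adjacent unique scores as candidates.

    Operating points are identical to :func:`build_roc`; only the numeric
    threshold values differ (a midpoint never coincides with an observed
    score, so the selected cutoff splits the data strictly).
    """
    s, y, excluded = _coerce_binary_truth(scores, truth)
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.array([])
    thresholds = np.concatenate(([uniq[0] - 1.0], mids, [np.inf]))
    pos, neg = s[y], s[~y]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return RocCurve(
        thresholds=thresholds,
        sens_at=sens,
        spec_at=spec,
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
        n_excluded=excluded,
    )


def auc(roc: RocCurve) -> float:
    """Trapezoidal area under the (1-specificity, sensitivity) curve.

    With candidate thresholds at every observed score this equals the
    Mann-Whitney probability with half credit for score ties.

    The curve is traversed in descending-threshold order (false-positive
    rate ascending); sorting by false-positive rate alone would scramble
    vertically stacked operating points.
    """
    fpr = (1.0 - roc.spec_at)[::-1]
    tpr = roc.sens_at[::-1]
    return float(np.trapezoid(tpr, fpr))


def youden_optimal(
    roc: RocCurve,
    tie_break: tuple[str, ...] = ("specificity", "smallest"),
) -> CutoffResult:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties in J are resolved by the ``tie_break`` sequence: "specificity"
    (prefer the more specific operating point), "sensitivity", and finally
    "smallest"/"largest" threshold.  The default — specificity, then the
    smallest threshold — yields deterministic output and favours specific
    operating points.
    """
    j = roc.sens_at + roc.spec_at - 1.0
    best = j.max()
    candidates = np.flatnonzero(np.isclose(j, best, rtol=0, atol=1e-12))
    for rule in tie_break:
        if len(candidates) == 1:
            break
        if rule == "specificity":
            key = roc.spec_at[candidates]
            candidates = candidates[np.isclose(key, key.max(), rtol=0, atol=1e-12)]
        elif rule == "sensitivity":
            key = roc.sens_at[candidates]
            candidates = candidates[np.isclose(key, key.max(), rtol=0, atol=1e-12)]
        elif rule == "smallest":
            candidates = candidates[:1]
        elif rule == "largest":
            candidates = candidates[-1:]
        else:
            raise InvalidInputError(f"unknown tie-break rule {rule!r}")
    idx = int(candidates[0])
    return CutoffResult(
        cutoff=float(roc.thresholds[idx]),
        youden_j=float(j[idx]),
        auc=auc(roc),
        sensitivity=float(roc.sens_at[idx]),
        specificity=float(roc.spec_at[idx]),
        n_pos=roc.n_pos,
        n_neg=roc.n_neg,
    )


class CutpointModel:
    """Youden-optimal cutpoint estimator for one (target, reference) pair.

    Parameters
    ----------
    scores : array-like
        Per-subject SUVR values.
    truth : array-like
        Paired standard-of-truth labels (anything :func:`as_status` accepts).
    target_region, reference_region, sot : str, optional
        Metadata carried into the results and summary table.

    Examples
    --------
    >>> model = CutpointModel([1.2, 1.3, 1.6, 1.8], ["negative", "negative",
    ...                                              "positive", "positive"])
    >>> res = model.fit()
    >>> res.cutoff
    1.6
    """

    def __init__(
        self,
        scores,
        truth,
        target_region: str | None = None,
        reference_region: str | None = None,
        sot: str | None = None,
    ):
        self.scores = np.asarray(scores, dtype=float)
        self.truth = list(truth)
        self.target_region = target_region
        self.reference_region = reference_region
        self.sot = sot

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        score_col: str = "suvr",
        truth_col: str = "truth",
        **meta,
    ) -> "CutpointModel":
        return cls(data[score_col].to_numpy(), data[truth_col].tolist(), **meta)

    def fit(
        self,
        candidates: str = "observed",
        tie_break: tuple[str, ...] = ("specificity", "smallest"),
    ) -> "CutpointResults":
        """Estimate the cutpoint.

        candidates="observed" uses the observed scores as thresholds
        (default; the selected cutoff is then an observed SUVR);
        "midpoint" uses midpoints between adjacent unique scores.
        """
        if candidates == "observed":
            roc = build_roc(self.scores, self.truth)
        elif candidates == "midpoint":
            roc = midpoint_roc(self.scores, self.truth)
        else:
            raise InvalidInputError(f"candidates must be 'observed' or 'midpoint', got {candidates!r}")
        result = replace(
            youden_optimal(roc, tie_break=tie_break),
            target_region=self.target_region,
            reference_region=self.reference_region,
            sot=self.sot,
        )
        return CutpointResults(self, roc, result)


class CutpointResults:
    """Fitted cutpoint with its ROC curve; supports summary and classification."""

    def __init__(self, model: CutpointModel, roc: RocCurve, result: CutoffResult):
        self.model = model
        self.roc = roc
        self.result = result

    # convenience accessors
    @property
    def cutoff(self) -> float:
        return self.result.cutoff

    @property
    def youden_j(self) -> float:
        return self.result.youden_j

    @property
    def auc(self) -> float:
        return self.result.auc

    def classify(self, scores) -> list[AmyloidStatus]:
        """Classify new scores at the fitted cutoff (positive iff >= cutoff)."""
        from .suvr import classify_scan

        return [classify_scan(s, self.result.cutoff) for s in np.atleast_1d(scores)]

    def summary(self) -> str:
        r = self.result
        lines = [
            "Youden-optimal SUVR cutpoint",
            "=" * 44,
            f"target region:     {r.target_region or '-'}",
            f"reference region:  {r.reference_region or '-'}",
            f"standard of truth: {r.sot or '-'}",
            f"n positive / negative: {r.n_pos} / {r.n_neg}",
            "-" * 44,
            f"cutoff (>= positive):  {r.cutoff:.4g}",
            f"Youden J:              {r.youden_j:.3f}",
            f"AUC (trapezoidal):     {r.auc:.3f}",
            f"sensitivity at cutoff: {r.sensitivity:.3f}",
            f"specificity at cutoff: {r.specificity:.3f}",
        ]
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curve with the selected operating point marked (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fpr = (1.0 - self.roc.spec_at)[::-1]
        ax.plot(fpr, self.roc.sens_at[::-1], drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls=":", c="gray")
        r = self.result
        ax.plot(1 - r.specificity, r.sensitivity, "o", c="C3")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"AUC = {r.auc:.3f}, cutoff = {r.cutoff:.3g}")
        return ax


def generate_cutoff_table(
    suvr: pd.DataFrame,
    scan_truth: pd.DataFrame,
    regional_truth: pd.DataFrame | None = None,
    sot_mode: str = "visual",
    candidates: str = "observed",
) -> pd.DataFrame:
    """Cutoffs for every (target region x reference region) pair.

    Mirrors the study design: composite cutoffs are generated against the
    scan-level truth (visual whole-brain BAPL classification, or
    histopathology), regional cutoffs against the per-region truth (visual
    RCTU classification) when ``regional_truth`` is supplied, else regional
    targets are skipped.

    Parameters
    ----------
    suvr
        Long table ``subject_id, reference_region, target_region, suvr``.
    scan_truth
        ``subject_id, status`` table (subject-level).
    regional_truth
        ``subject_id, region, status`` table keyed by visual region names.
    sot_mode
        "visual" (labels rows visual_bapl / visual_rctu) or "histopathology".

    Returns a DataFrame ``target_region, reference_region, cutoff, auc,
    youden_j, sensitivity, specificity, n_pos, n_neg, n_excluded, sot``.
    """
    import logging

    log = logging.getLogger(__name__)
    scan_map = dict(zip(scan_truth["subject_id"], scan_truth["status"]))
    regional_map: dict[tuple, str] = {}
    if regional_truth is not None:
        regional_map = {
            (r.subject_id, r.region): r.status for r in regional_truth.itertuples()
        }
    rows = []
    for target in CUTOFF_TARGETS:
        if target != "composite" and regional_truth is None:
            continue
        for rr in REFERENCE_REGIONS:
            block = suvr[
                (suvr["target_region"] == target) & (suvr["reference_region"] == rr)
            ]
            if block.empty:
                continue
            if target == "composite":
                truth = [scan_map.get(s, math.nan) for s in block["subject_id"]]
                sot = "visual_bapl" if sot_mode == "visual" else "histopathology"
            else:
                vr = TARGET_TO_VISUAL[target]
                truth = [regional_map.get((s, vr), math.nan) for s in block["subject_id"]]
                sot = "visual_rctu" if sot_mode == "visual" else "histopathology"
            n_missing = sum(pd.isna(t) if not isinstance(t, str) else False for t in truth)
            if n_missing:
                log.warning(
                    "%s/%s: %d subjects lack truth labels and are excluded",
                    target, rr, n_missing,
                )
            res = (
                CutpointModel(
                    block["suvr"].to_numpy(),
                    truth,
                    target_region=target,
                    reference_region=rr,
                    sot=sot,
                )
                .fit(candidates=candidates)
                .result
            )
            rows.append(
                {
                    "target_region": target,
                    "reference_region": rr,
                    "cutoff": res.cutoff,
                    "auc": res.auc,
                    "youden_j": res.youden_j,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                    "n_pos": res.n_pos,
                    "n_neg": res.n_neg,
                    "sot": res.sot,
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["target_region", "reference_region"])
        .reset_index(drop=True)
    )
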