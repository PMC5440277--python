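"""Diagnostic-performance metrics with exact binomial confidence intervals.

Sensitivity, specificity, accuracy and percent agreement are binomial
proportions; their 95% intervals use the exact Clopper-Pearson construction
from beta-distribution quantiles.  Accuracy differences between classifiers
are compared with a Pearson chi-squared test (no continuity correction,
classifiers treated as independent samples) and corrected for multiplicity
with the Bonferroni-Holm step-down procedure.  Report percentages are
rounded half-up to integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import AmyloidStatus, InvalidInputError, as_status


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    excluded_missing: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with its exact (Clopper-Pearson) interval."""

    numerator: int
    denominator: int
    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def as_percent(self) -> tuple[float, float, float]:
        """(point, low, high) on the 0-100 scale, unrounded."""
        return 100 * self.point, 100 * self.ci_low, 100 * self.ci_high


@dataclass
class PairwiseComparison:
    label_a: str
    label_b: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    significant: bool | None = None


def confusion(predicted: Sequence, reference: Sequence) -> ConfusionSummary:
    """2x2 tally of paired calls; indeterminate/missing pairs excluded and counted."""
    pred = [as_status(p) for p in predicted]
    ref = [as_status(r) for r in reference]
    if len(pred) != len(ref):
        raise InvalidInputError("predicted and reference must be paired")
    tp = fp = tn = fn = excluded = 0
    for p, r in zip(pred, ref):
        if AmyloidStatus.INDETERMINATE in (p, r):
            excluded += 1
        elif r is AmyloidStatus.POSITIVE:
            tp += p is AmyloidStatus.POSITIVE
            fn += p is AmyloidStatus.NEGATIVE
        else:
            tn += p is AmyloidStatus.NEGATIVE
            fp += p is AmyloidStatus.POSITIVE
    if tp + fp + tn + fn == 0:
        raise InvalidInputError("no determinate pairs to tally")
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn, excluded_missing=excluded)


def clopper_pearson(x: int, n: int, level: float = 0.95) -> ProportionEstimate:
    """Exact two-sided binomial interval from beta quantiles.

    lower = Beta_{alpha/2}(x, n-x+1) for x > 0, else 0;
    upper = Beta_{1-alpha/2}(x+1, n-x) for x < n, else 1.
    """
    if not (0 <= x <= n) or n < 1:
        raise InvalidInputError(f"invalid counts x={x}, n={n}")
    alpha = 1.0 - level
    lo = float(stats.beta.ppf(alpha / 2, x, n - x + 1)) if x > 0 else 0.0
    hi = float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x)) if x < n else 1.0
    return ProportionEstimate(
        numerator=int(x), denominator=int(n), point=x / n, ci_low=lo, ci_high=hi, level=level
    )


def _proportion(x: int, n: int, level: float, what: str) -> ProportionEstimate:
    if n == 0:
        raise InvalidInputError(f"{what} undefined: zero denominator")
    return clopper_pearson(x, n, level)


def sensitivity(cs: ConfusionSummary, level: float = 0.95) -> ProportionEstimate:
    """tp / (tp + fn) with exact CI."""
    return _proportion(cs.tp, cs.tp + cs.fn, level, "sensitivity")


def specificity(cs: ConfusionSummary, level: float = 0.95) -> ProportionEstimate:
    """tn / (tn + fp) with exact CI."""
    return _proportion(cs.tn, cs.tn + cs.fp, level, "specificity")


def accuracy(cs: ConfusionSummary, level: float = 0.95) -> ProportionEstimate:
    """(tp + tn) / n with exact CI."""
    return _proportion(cs.tp + cs.tn, cs.n, level, "accuracy")


def percent_agreement(a: Sequence, b: Sequence, level: float = 0.95) -> ProportionEstimate:
    """Fraction of concordant determinate pairs, with exact CI.

    Symmetric in its arguments — neither list is treated as truth.  Pairs
    where either call is indeterminate/missing are excluded.
    """
    sa = [as_status(x) for x in a]
    sb = [as_status(x) for x in b]
    if len(sa) != len(sb):
        raise InvalidInputError("lists must be paired")
    pairs = [
        (p, q)
        for p, q in zip(sa, sb)
        if AmyloidStatus.INDETERMINATE not in (p, q)
    ]
    if not pairs:
        raise InvalidInputError("no determinate pairs to compare")
    agree = sum(p is q for p, q in pairs)
    return clopper_pearson(agree, len(pairs), level)


def chisq_2x2(
    correct_a: int, n_a: int, correct_b: int, n_b: int,
    label_a: str = "a", label_b: str = "b",
) -> PairwiseComparison:
    """Pearson chi-squared (df=1, no continuity correction) comparing two
    correct/incorrect proportions as independent samples.

    A zero expected cell (all-correct or all-incorrect margins) leaves the
    statistic undefined (NaN).
    """
    if n_a < 1 or n_b < 1 or not (0 <= correct_a <= n_a) or not (0 <= correct_b <= n_b):
        raise InvalidInputError("invalid counts")
    table = np.array(
        [[correct_a, n_a - correct_a], [correct_b, n_b - correct_b]], dtype=float
    )
    expected = table.sum(axis=1, keepdims=True) * table.sum(axis=0, keepdims=True) / table.sum()
    if np.any(expected == 0):
        return PairwiseComparison(label_a, label_b, float("nan"), float("nan"))
    stat = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return PairwiseComparison(label_a, label_b, stat, p)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, order-preserving.

    Adjusted values are >= raw, <= plain Bonferroni, capped at 1, and
    monotone in the raw ordering.  Delegates to statsmodels' multipletests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="holm")[1]


def pairwise_comparisons(
    labels: Sequence[str],
    correct: Sequence[int],
    totals: Sequence[int],
    alpha: float = 0.05,
) -> list[PairwiseComparison]:
    """All pairwise chi-squared accuracy comparisons with Holm correction.

    Comparisons with an undefined statistic (zero expected cell) are carried
    through with NaN p-values and excluded from the adjustment.
    """
    comps: list[PairwiseComparison] = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            comps.append(
                chisq_2x2(
                    correct[i], totals[i], correct[j], totals[j],
                    label_a=labels[i], label_b=labels[j],
                )
            )
    defined = [c for c in comps if np.isfinite(c.p_raw)]
    if defined:
        adjusted = holm_adjust([c.p_raw for c in defined])
        for c, p_adj in zip(defined, adjusted):
            c.p_adjusted = float(p_adj)
            c.significant = bool(p_adj < alpha)
    return comps


class ValidationResults:
    """Confusion-matrix summary of one classifier against a reference,
    with exact intervals and a formatted report table."""

    def __init__(self, cs: ConfusionSummary, level: float = 0.95):
        self.confusion = cs
        self.level = level
        self.sensitivity = sensitivity(cs, level)
        self.specificity = specificity(cs, level)
        self.accuracy = accuracy(cs, level)

    def summary(self) -> str:
        from .core import round_half_up

        def fmt(est: ProportionEstimate) -> str:
            p, lo, hi = est.as_percent()
            return (
                f"{round_half_up(p):3.0f} ({round_half_up(lo):.0f}-{round_half_up(hi):.0f})"
                f"  [{est.numerator}/{est.denominator}]"
            )

        cs = self.confusion
        return "\n".join(
            [
                "Classification vs reference",
                "=" * 44,
                f"TP {cs.tp}  FP {cs.fp}  TN {cs.tn}  FN {cs.fn}"
                f"  (excluded {cs.excluded_missing})",
                f"sensitivity: {fmt(self.sensitivity)}",
                f"specificity: {fmt(self.specificity)}",
                f"accuracy:    {fmt(self.accuracy)}",
            ]
        )


def validate_classification(
    predicted: Sequence, reference: Sequence, level: float = 0.95
) -> ValidationResults:
    """Confusion summary plus sensitivity/specificity/accuracy with exact CIs."""
    return ValidationResults(confusion(predicted, reference), level=level)
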