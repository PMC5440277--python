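"""Visual assessment: regional uptake scores, whole-brain load, majority reads.

Readers score tracer uptake in four cortical regions on the 3-level regional
cortical tracer uptake (RCTU) scale (1 = no uptake, 2 = moderate,
3 = pronounced), from which a whole-brain amyloid plaque load (BAPL) score is
derived: the scan-level score is driven by the most affected region (any
region at 3 gives BAPL 3, else any region at 2 gives BAPL 2, else BAPL 1).
A scan is visually negative iff BAPL = 1.  Multiple readers are aggregated
by strict majority; even splits are reported as indeterminate, never broken.

The RCTU-to-BAPL mapping is isolated in a single function so an alternative
rule can be swapped in if a site uses a different convention.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd

from .core import AmyloidStatus, InvalidInputError, SchemaError, as_status, is_missing
from .regions import VISUAL_REGIONS

_VALID_SCORES = {1, 2, 3}


def _check_score(score: int, what: str = "score") -> int:
    if is_missing(score):
        raise SchemaError(f"missing {what}")
    s = int(score)
    if s != score or s not in _VALID_SCORES:
        raise SchemaError(f"{what} must be in {{1, 2, 3}}, got {score!r}")
    return s


def rctu_to_bapl(rctu: Mapping[str, int]) -> int:
    """Whole-brain plaque-load score from the four regional uptake scores."""
    if set(rctu) != set(VISUAL_REGIONS):
        raise SchemaError(
            f"RCTU must cover exactly {sorted(VISUAL_REGIONS)}, got {sorted(rctu)}"
        )
    scores = [_check_score(rctu[r], f"RCTU[{r}]") for r in VISUAL_REGIONS]
    return max(scores)


def bapl_to_binary(bapl: int) -> AmyloidStatus:
    """Scan negative iff BAPL = 1; BAPL 2 or 3 is positive."""
    return AmyloidStatus.NEGATIVE if _check_score(bapl, "BAPL") == 1 else AmyloidStatus.POSITIVE


def rctu_to_binary(rctu_score: int) -> AmyloidStatus:
    """Region negative iff RCTU = 1; RCTU 2 or 3 is positive."""
    s = _check_score(rctu_score, "RCTU")
    return AmyloidStatus.NEGATIVE if s == 1 else AmyloidStatus.POSITIVE


@dataclass(frozen=True)
class ReaderAssessment:
    """One reader's regional scores with the derived scan-level result."""

    subject_id: str
    reader_id: str
    rctu: Mapping[str, int]
    reader_class: str = "expert"  # metadata only; does not alter aggregation
    bapl: int = field(init=False)
    binary: AmyloidStatus = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bapl", rctu_to_bapl(self.rctu))
        object.__setattr__(self, "binary", bapl_to_binary(self.bapl))


@dataclass(frozen=True)
class MajorityResult:
    subject_id: str | None
    votes_negative: int
    votes_positive: int
    status: AmyloidStatus


def majority_read(
    reads: Sequence[AmyloidStatus | str | None], subject_id: str | None = None
) -> MajorityResult:
    """Strict-majority aggregate of binary reads; a draw is indeterminate.

    Indeterminate/missing individual reads are excluded from the tallies.
    """
    statuses = [as_status(r) for r in reads]
    pos = sum(s is AmyloidStatus.POSITIVE for s in statuses)
    neg = sum(s is AmyloidStatus.NEGATIVE for s in statuses)
    if pos + neg == 0:
        raise InvalidInputError("majority read requires at least one non-missing read")
    if pos > neg:
        status = AmyloidStatus.POSITIVE
    elif neg > pos:
        status = AmyloidStatus.NEGATIVE
    else:
        status = AmyloidStatus.INDETERMINATE
    return MajorityResult(subject_id, neg, pos, status)


def _check_reads_table(reads: pd.DataFrame) -> None:
    required = {"subject_id", "reader_id", "region", "rctu"}
    if not required.issubset(reads.columns):
        raise SchemaError(f"reads table needs columns {sorted(required)}")


def scan_majority(reads: pd.DataFrame) -> pd.DataFrame:
    """Per-subject majority over readers' scan-level (BAPL-derived) calls.

    ``reads`` is long: one row per (subject, reader, region) RCTU score.
    Readers missing any of the four regions for a subject contribute no vote.
    Returns ``subject_id, votes_negative, votes_positive, status``.
    """
    _check_reads_table(reads)
    rows = []
    for subject_id, sub in reads.groupby("subject_id", sort=True):
        votes: list[AmyloidStatus] = []
        for _, reader_scores in sub.groupby("reader_id"):
            rctu = dict(zip(reader_scores["region"], reader_scores["rctu"]))
            if set(rctu) != set(VISUAL_REGIONS) or any(is_missing(v) for v in rctu.values()):
                continue
            votes.append(bapl_to_binary(rctu_to_bapl(rctu)))
        result = majority_read(votes, subject_id=str(subject_id))
        rows.append(
            {
                "subject_id": subject_id,
                "votes_negative": result.votes_negative,
                "votes_positive": result.votes_positive,
                "status": result.status.value,
            }
        )
    return pd.DataFrame(rows)


def regional_majority(reads: pd.DataFrame) -> pd.DataFrame:
    """Per-(subject, region) majority over readers' RCTU-derived calls.

    This is the per-region standard of truth used when generating regional
    (as opposed to composite) SUVR cutoffs.  Returns ``subject_id, region,
    votes_negative, votes_positive, status``.
    """
    _check_reads_table(reads)
    rows = []
    grouped = reads.dropna(subset=["rctu"]).groupby(["subject_id", "region"], sort=True)
    for (subject_id, region), sub in grouped:
        votes = [rctu_to_binary(s) for s in sub["rctu"]]
        result = majority_read(votes, subject_id=str(subject_id))
        rows.append(
            {
                "subject_id": subject_id,
                "region": region,
                "votes_negative": result.votes_negative,
                "votes_positive": result.votes_positive,
                "status": result.status.value,
            }
        )
    return pd.DataFrame(rows)


def per_reader_status(reads: pd.DataFrame) -> pd.DataFrame:
    """Scan-level binary call for each individual reader.

    Returns ``subject_id, reader_id, reader_class, status`` (reader_class
    passed through when present, else 'expert').  Used to compare single
    readers — e.g. naive versus expert panels — against histopathology.
    """
    _check_reads_table(reads)
    rows = []
    for (subject_id, reader_id), sub in reads.groupby(["subject_id", "reader_id"], sort=True):
        rctu = dict(zip(sub["region"], sub["rctu"]))
        if set(rctu) != set(VISUAL_REGIONS) or any(is_missing(v) for v in rctu.values()):
            continue
        reader_class = (
            sub["reader_class"].iloc[0] if "reader_class" in sub.columns else "expert"
        )
        rows.append(
            {
                "subject_id": subject_id,
                "reader_id": reader_id,
                "reader_class": reader_class,
                "status": bapl_to_binary(rctu_to_bapl(rctu)).value,
            }
        )
    return pd.DataFrame(rows)
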