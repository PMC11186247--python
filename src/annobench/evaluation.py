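"""Exact-boundary CDS-level evaluation of a predicted annotation.

A predicted CDS is a true positive (TP) iff an interval with identical
(seqid, start, end, strand) exists in the reference; every other prediction
is a false positive (FP). False positives split into overlapping predicted
exons (OPE: share >=1 bp with some same-seqid/same-strand reference CDS)
and wrong exons (WE: overlap nothing). On the reference side, unmatched
intervals are false negatives (FN); an FN overlapped by no prediction is
additionally a missed exon (ME).

Metrics::

    Sn = TP/(TP+FN)        Sp = TP/(TP+FP)       F1 = 2*Sn*Sp/(Sn+Sp)
    OScore = OPE/FP        WScore = WE/FP        MScore = ME/(TP+FN)

Ratios with a zero denominator are reported as ``None`` (undefined), never
as 0, and are meant to be excluded from downstream statistics.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from intervaltree import IntervalTree

from .annotation import AnnotationSet, ExonInterval, unique_cds_intervals

__all__ = [
    "CdsEvalResult",
    "classify_predicted",
    "classify_reference",
    "evaluate_cds",
    "evaluate_cds_intervals",
]

TP, FN, OPE, WE = "TP", "FN", "OPE", "WE"


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


@dataclass(frozen=True)
class CdsEvalResult:
    """Counts and derived CDS-level metrics for one reference/prediction pair."""

    tp: int
    fp: int
    fn: int
    ope: int
    we: int
    me: int

    def __post_init__(self) -> None:
        if self.fp != self.ope + self.we:
            raise ValueError("fp must equal ope + we")
        if self.me > self.fn:
            raise ValueError("me cannot exceed fn")

    @property
    def sn(self) -> float | None:
        return _safe_div(self.tp, self.tp + self.fn)

    @property
    def sp(self) -> float | None:
        return _safe_div(self.tp, self.tp + self.fp)

    @property
    def f1(self) -> float | None:
        sn, sp = self.sn, self.sp
        if sn is None or sp is None or sn + sp == 0:
            return None
        return 2 * sn * sp / (sn + sp)

    @property
    def oscore(self) -> float | None:
        return _safe_div(self.ope, self.fp)

    @property
    def wscore(self) -> float | None:
        return _safe_div(self.we, self.fp)

    @property
    def mscore(self) -> float | None:
        return _safe_div(self.me, self.tp + self.fn)

    def as_dict(self) -> dict[str, float | int | None]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "ope": self.ope,
            "we": self.we,
            "me": self.me,
            "sn": self.sn,
            "sp": self.sp,
            "f1": self.f1,
            "oscore": self.oscore,
            "wscore": self.wscore,
            "mscore": self.mscore,
        }


def _overlap_index(
    intervals: Iterable[ExonInterval],
) -> Mapping[tuple[str, str], IntervalTree]:
    """Strand-aware interval index; tree coordinates are half-open [start, end+1)."""
    index: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for iv in intervals:
        index[(iv.seqid, iv.strand)].addi(iv.start, iv.end + 1, iv)
    return index


def _overlaps_any(
    index: Mapping[tuple[str, str], IntervalTree],
    iv: ExonInterval,
    min_overlap: int,
) -> bool:
    tree = index.get((iv.seqid, iv.strand))
    if tree is None:
        return False
    if min_overlap == 1:
        return bool(tree.overlap(iv.start, iv.end + 1))
    for hit in tree.overlap(iv.start, iv.end + 1):
        shared = min(iv.end, hit.end - 1) - max(iv.start, hit.begin) + 1
        if shared >= min_overlap:
            return True
    return False


def classify_predicted(
    ref_cds: set[ExonInterval],
    pred_cds: set[ExonInterval],
    min_overlap: int = 1,
) -> dict[ExonInterval, str]:
    """Label each predicted interval TP, OPE or WE against the reference.

    Overlap requires same seqid AND same strand; an antisense prediction
    over a reference exon does not capture the coding region and is WE.
    """
    ref_index = _overlap_index(ref_cds)
    labels: dict[ExonInterval, str] = {}
    for iv in pred_cds:
        if iv in ref_cds:
            labels[iv] = TP
        elif _overlaps_any(ref_index, iv, min_overlap):
            labels[iv] = OPE
        else:
            labels[iv] = WE
    return labels


def classify_reference(
    ref_cds: set[ExonInterval],
    pred_cds: set[ExonInterval],
    min_overlap: int = 1,
) -> dict[ExonInterval, tuple[str, bool]]:
    """Label each reference interval (TP or FN, is_missed_exon)."""
    pred_index = _overlap_index(pred_cds)
    labels: dict[ExonInterval, tuple[str, bool]] = {}
    for iv in ref_cds:
        if iv in pred_cds:
            labels[iv] = (TP, False)
        else:
            missed = not _overlaps_any(pred_index, iv, min_overlap)
            labels[iv] = (FN, missed)
    return labels


def evaluate_cds_intervals(
    ref_cds: set[ExonInterval],
    pred_cds: set[ExonInterval],
    min_overlap: int = 1,
) -> CdsEvalResult:
    """Evaluate deduplicated interval sets directly."""
    pred_labels = classify_predicted(ref_cds, pred_cds, min_overlap)
    ref_labels = classify_reference(ref_cds, pred_cds, min_overlap)
    tp = sum(1 for lab in pred_labels.values() if lab == TP)
    ope = sum(1 for lab in pred_labels.values() if lab == OPE)
    we = sum(1 for lab in pred_labels.values() if lab == WE)
    fn = sum(1 for lab, _ in ref_labels.values() if lab == FN)
    me = sum(1 for _, missed in ref_labels.values() if missed)
    return CdsEvalResult(tp=tp, fp=ope + we, fn=fn, ope=ope, we=we, me=me)


def evaluate_cds(
    ref: AnnotationSet,
    pred: AnnotationSet,
    min_overlap: int = 1,
) -> CdsEvalResult:
    """Evaluate a predicted annotation at the CDS level.

    Operates on unique (seqid, start, end, strand) intervals so shared
    exons across isoforms count once. Seqids present in only one of the two
    annotations are still evaluated: predictions there become WE, reference
    intervals there become ME.
    """
    return evaluate_cds_intervals(
        unique_cds_intervals(ref), unique_cds_intervals(pred), min_overlap
    )
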