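"""CNV-call concordance against an orthogonal truth source.

Two summary rates:

* sensitivity — detected truth CNVs / all truth CNVs;
* support rate — supported calls / all calls. (Validation studies of
  array CNV calling often label this quantity "specificity"; it is a
  precision, and it is implemented here under its honest definition.)

Overlap criterion throughout: at least one base pair of same-type,
same-chromosome overlap. Percentages round half-up to one decimal place.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from intervaltree import IntervalTree

from .types import CnvCall


def _pct(numerator: float, denominator: float) -> float:
    """100 * numerator / denominator, rounded half-up to one decimal."""
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def sensitivity(truth_count: int, detected_count: int) -> float:
    """Percent of truth CNVs that were detected, to one decimal."""
    if truth_count <= 0:
        raise ValueError("truth_count must be positive")
    if not 0 <= detected_count <= truth_count:
        raise ValueError("detected_count must lie in [0, truth_count]")
    return _pct(detected_count, truth_count)


def support_rate(called_count: int, unsupported_count: int) -> float:
    """Percent of calls corroborated by the truth source, to one decimal."""
    if called_count <= 0:
        raise ValueError("called_count must be positive")
    if not 0 <= unsupported_count <= called_count:
        raise ValueError("unsupported_count must lie in [0, called_count]")
    return _pct(called_count - unsupported_count, called_count)


def proportion_report(numerator: int, denominator: int) -> float:
    """Plain percentage to one decimal (validation-style proportions)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    return _pct(numerator, denominator)


def match_calls(
    calls: list[CnvCall], truth: list[CnvCall], by_sample: bool = False
) -> list[bool]:
    """Per-call supported label: same-type truth overlap of >= 1 bp.

    By default sample identity is ignored — truth intervals are matched
    by locus and type, as when screening a call set against a published
    CNV map. With ``by_sample=True`` a call is only supported by a truth
    interval recorded in the same individual, the appropriate semantics
    for diagnostic-truth evaluation (a carrier's known CNV must be called
    in that carrier).
    """
    trees: dict[tuple, IntervalTree] = defaultdict(IntervalTree)
    for t in truth:
        key = (t.sample_id, t.chrom, t.cnv_type) if by_sample else (t.chrom, t.cnv_type)
        trees[key].addi(t.start, t.end + 1)
    out = []
    for c in calls:
        key = (c.sample_id, c.chrom, c.cnv_type) if by_sample else (c.chrom, c.cnv_type)
        out.append(bool(trees.get(key, IntervalTree()).overlap(c.start, c.end + 1)))
    return out


@dataclass(frozen=True)
class ConcordanceReport:
    n_truth: int
    n_detected: int
    n_called: int
    n_unsupported: int
    sensitivity: float  # percent
    support_rate: float  # percent

    def __post_init__(self) -> None:
        if self.n_detected > self.n_truth or self.n_unsupported > self.n_called:
            raise ValueError("inconsistent concordance counts")


def evaluate_concordance(
    calls: list[CnvCall], truth: list[CnvCall], by_sample: bool = False
) -> ConcordanceReport:
    """Full two-way comparison of a call set against a truth set.

    Detection is per truth CNV (any same-type overlapping call) and
    support is per call (any same-type overlapping truth CNV);
    ``by_sample`` restricts matches to the same individual.
    """
    if not truth or not calls:
        raise ValueError("both calls and truth must be non-empty")
    supported = match_calls(calls, truth, by_sample=by_sample)
    detected = match_calls(truth, calls, by_sample=by_sample)
    n_truth, n_called = len(truth), len(calls)
    n_detected = sum(detected)
    n_unsupported = n_called - sum(supported)
    return ConcordanceReport(
        n_truth=n_truth,
        n_detected=n_detected,
        n_called=n_called,
        n_unsupported=n_unsupported,
        sensitivity=sensitivity(n_truth, n_detected),
        support_rate=support_rate(n_called, n_unsupported),
    )
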