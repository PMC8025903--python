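"""Queue ranking and score summaries.

Cases are ranked from lowest to highest total score: rank 1 is the highest
surgical priority. Ties on the total are broken by the disease subtotal
(ascending — the more time-sensitive disease goes first) and then by case id,
so a queue is fully deterministic.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .records import TOTAL_BOUNDS, CaseRecord, ScoreSheet

TIER_ORDER = ("high", "intermediate", "low")


@dataclass(frozen=True)
class QueueEntry:
    case_id: str
    total: float
    procedure_subtotal: float
    disease_subtotal: float
    patient_subtotal: float
    rank: int  # 1-based; 1 = highest priority = lowest total


@dataclass(frozen=True)
class AggregateScore:
    """Per-case score aggregated over raters (used by the ``mean`` policy)."""

    case_id: str
    total: float
    procedure_subtotal: float
    disease_subtotal: float
    patient_subtotal: float


@dataclass(frozen=True)
class Stats:
    median: float
    min: float
    max: float


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    total: Stats
    procedure: Stats
    disease: Stats
    patient: Stats


@dataclass(frozen=True)
class TierCrosswalk:
    summaries: Mapping[str, GroupSummary]  # keyed by tier
    monotonic: bool  # median(high) <= median(intermediate) <= median(low)


def rank_cases(sheets: Sequence) -> list[QueueEntry]:
    """Rank one score per case into a queue (ascending by total).

    Accepts :class:`~ments.records.ScoreSheet` or :class:`AggregateScore`
    objects; exactly one entry per case is required.
    """
    seen = set()
    for s in sheets:
        if s.case_id in seen:
            raise ValueError(f"duplicate case_id {s.case_id!r} in ranking input")
        seen.add(s.case_id)
    ordered = sorted(sheets, key=lambda s: (s.total, s.disease_subtotal, str(s.case_id)))
    return [
        QueueEntry(
            case_id=s.case_id,
            total=s.total,
            procedure_subtotal=s.procedure_subtotal,
            disease_subtotal=s.disease_subtotal,
            patient_subtotal=s.patient_subtotal,
            rank=i + 1,
        )
        for i, s in enumerate(ordered)
    ]


def aggregate_sheets(sheets: Iterable[ScoreSheet], policy: str = "attending") -> list:
    """Collapse multi-rater sheets to one score per case.

    ``attending`` keeps the attending rater's sheet; ``mean`` averages the
    totals and subtotals across raters (non-integer results are kept as-is,
    ranking does not require integer scores).
    """
    by_case: dict[str, list[ScoreSheet]] = {}
    for s in sheets:
        by_case.setdefault(s.case_id, []).append(s)
    out: list = []
    for cid, group in by_case.items():
        if policy == "attending":
            att = [s for s in group if s.rater_role == "attending"]
            if len(att) != 1:
                raise ValueError(
                    f"case {cid!r}: expected exactly one attending sheet, got {len(att)}"
                )
            out.append(att[0])
        elif policy == "mean":
            out.append(
                AggregateScore(
                    case_id=cid,
                    total=float(np.mean([s.total for s in group])),
                    procedure_subtotal=float(np.mean([s.procedure_subtotal for s in group])),
                    disease_subtotal=float(np.mean([s.disease_subtotal for s in group])),
                    patient_subtotal=float(np.mean([s.patient_subtotal for s in group])),
                )
            )
        else:
            raise ValueError(f"unknown aggregation policy {policy!r}")
    return out


def _stats(values: Sequence[float]) -> Stats:
    # statistics.median uses the midpoint of the two central values for even n
    return Stats(median=float(statistics.median(values)),
                 min=float(min(values)), max=float(max(values)))


def _summary(label: str, group: Sequence) -> GroupSummary:
    return GroupSummary(
        label=label,
        n=len(group),
        total=_stats([s.total for s in group]),
        procedure=_stats([s.procedure_subtotal for s in group]),
        disease=_stats([s.disease_subtotal for s in group]),
        patient=_stats([s.patient_subtotal for s in group]),
    )


def groups_from_cases(cases: Iterable[CaseRecord], attribute: str) -> dict:
    """Map case_id -> value of ``attribute`` for use with summarize_scores."""
    groups = {}
    for c in cases:
        v = getattr(c, attribute)
        if v is None:
            raise ValueError(f"case {c.case_id!r}: attribute {attribute!r} is unset")
        groups[c.case_id] = str(v)
    return groups


def summarize_scores(sheets: Sequence, groups: Optional[Mapping[str, str]] = None
                     ) -> list[GroupSummary]:
    """Median and range of total and component scores, overall and per group.

    Returns an ``all`` row first, then one row per observed group (sorted by
    label). ``groups`` maps case_id to a group label; every case must resolve.
    """
    if not sheets:
        raise ValueError("no score sheets to summarize")
    out = [_summary("all", sheets)]
    if groups is not None:
        by_label: dict[str, list] = {}
        for s in sheets:
            if s.case_id not in groups:
                raise ValueError(f"case {s.case_id!r} has no group label")
            by_label.setdefault(groups[s.case_id], []).append(s)
        out.extend(_summary(lbl, grp) for lbl, grp in sorted(by_label.items()))
    return out


def score_histogram(sheets: Sequence, lo: int = TOTAL_BOUNDS[0],
                    hi: int = TOTAL_BOUNDS[1]) -> tuple[np.ndarray, np.ndarray]:
    """Integer-binned counts of totals over the instrument's range.

    Returns ``(edges, counts)`` with one unit-width bin per attainable total
    (edges ``lo, lo+1, ..., hi+1``); counts sum to the number of sheets.
    """
    totals = np.asarray([s.total for s in sheets], dtype=float)
    if totals.size and (totals.min() < lo or totals.max() > hi):
        raise ValueError(
            f"total outside [{lo}, {hi}] encountered — upstream invariant breach"
        )
    edges = np.arange(lo, hi + 2)
    counts, _ = np.histogram(totals, bins=edges)
    return edges, counts


def tier_crosswalk(sheets: Sequence, tiers: Mapping[str, str]) -> TierCrosswalk:
    """Per-acuity-tier summaries plus a monotonicity flag.

    The instrument agrees with a diagnosis-driven three-tier acuity schema
    when median totals rise as acuity falls: median(high) <=
    median(intermediate) <= median(low).
    """
    by_tier: dict[str, list] = {}
    for s in sheets:
        tier = tiers.get(s.case_id)
        if tier is None:
            raise ValueError(f"case {s.case_id!r} has no acuity tier label")
        if tier not in TIER_ORDER:
            raise ValueError(f"case {s.case_id!r}: unknown tier {tier!r}")
        by_tier.setdefault(tier, []).append(s)
    summaries = {t: _summary(t, grp) for t, grp in by_tier.items()}
    medians = [summaries[t].total.median for t in TIER_ORDER if t in summaries]
    monotonic = all(a <= b for a, b in zip(medians, medians[1:]))
    return TierCrosswalk(summaries=summaries, monotonic=monotonic)
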