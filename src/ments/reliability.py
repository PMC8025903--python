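"""Inter-rater reliability: two-way ANOVA decomposition, intraclass
correlation for absolute agreement, interpretation bands, and a
rank-consistency statistic.

The design is a fully crossed two-way layout without replication: n cases
(random subjects) each scored once by each of k raters (random raters; here
typically a trainee/attending pair). The intraclass correlation coefficient
(ICC) reported is the two-way random-effects, absolute-agreement, single-
rater form — ICC(A,1) in McGraw-Wong notation, ICC(2,1) in Shrout-Fleiss —

    ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

where MS_R, MS_C, MS_E are the between-subject, between-rater and residual
mean squares. Absolute agreement (rather than consistency) counts a
systematic shift between raters as disagreement, which is the conservative
choice for a triage score whose absolute value drives scheduling.

Estimates are interpreted on the conventional Cicchetti bands:
poor < 0.40, fair 0.40-0.59, good 0.60-0.74, excellent >= 0.75.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import DegenerateDataError
from .records import ScoreSheet

logger = logging.getLogger(__name__)

CICCHETTI_BANDS = (
    (0.40, "poor"),
    (0.60, "fair"),
    (0.75, "good"),
    (math.inf, "excellent"),
)


@dataclass(frozen=True)
class RatingMatrix:
    """n subjects x k raters table of totals, no missing cells."""

    subjects: tuple
    raters: tuple
    values: np.ndarray  # shape (n, k), float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n, k = v.shape
        if n != len(self.subjects) or k != len(self.raters):
            raise ValueError("values shape does not match subject/rater labels")
        if n < 2 or k < 2:
            raise ValueError(f"need at least 2 subjects and 2 raters, got {n} x {k}")
        if not np.isfinite(v).all():
            raise ValueError("rating matrix contains missing or non-finite cells")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_values(cls, values) -> "RatingMatrix":
        v = np.asarray(values, dtype=float)
        return cls(subjects=tuple(range(v.shape[0])),
                   raters=tuple(range(v.shape[1])), values=v)

    @classmethod
    def from_sheets(cls, sheets: Iterable[ScoreSheet],
                    raters: Sequence[str] = ("trainee", "attending")
                    ) -> "RatingMatrix":
        """Pivot score sheets to a case x rater-role matrix of totals.

        Cases missing a rating from any requested rater are dropped with a
        logged count (listwise deletion).
        """
        by_case: dict[str, dict[str, float]] = {}
        for s in sheets:
            by_case.setdefault(s.case_id, {})[s.rater_role] = float(s.total)
        complete, dropped = [], 0
        for cid, row in by_case.items():
            if all(r in row for r in raters):
                complete.append((cid, [row[r] for r in raters]))
            else:
                dropped += 1
        if dropped:
            logger.info("rating matrix: dropped %d case(s) with incomplete "
                        "rater pairs", dropped)
        if len(complete) < 2:
            raise ValueError(
                f"need at least 2 complete rater pairs, got {len(complete)}"
            )
        return cls(subjects=tuple(c for c, _ in complete), raters=tuple(raters),
                   values=np.array([v for _, v in complete], dtype=float))


@dataclass(frozen=True)
class AnovaDecomposition:
    ms_rows: float  # between-subjects mean square
    ms_cols: float  # between-raters mean square
    ms_error: float  # residual mean square
    df_rows: int
    df_cols: int
    df_error: int


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    form: str
    decomposition: AnovaDecomposition
    band: str


def anova_decompose(matrix: RatingMatrix) -> AnovaDecomposition:
    """Two-way crossed ANOVA without replication on the rating matrix."""
    x = matrix.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_error = float((resid ** 2).sum())
    return AnovaDecomposition(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_error=ss_error / ((n - 1) * (k - 1)),
        df_rows=n - 1,
        df_cols=k - 1,
        df_error=(n - 1) * (k - 1),
    )


def interpret_icc(estimate: float) -> str:
    """Cicchetti interpretation band for an ICC estimate."""
    if not math.isfinite(estimate):
        raise ValueError(f"ICC estimate must be finite, got {estimate}")
    for upper, band in CICCHETTI_BANDS:
        if estimate < upper:
            return band
    raise AssertionError("unreachable")


def icc_absolute_agreement(matrix: RatingMatrix,
                           measure: str = "single") -> ICCResult:
    """Two-way random-effects, absolute-agreement ICC.

    ``measure='single'`` (default) estimates the reliability of one rater's
    score — the relevant form when a case is scored by one clinician in
    practice. ``measure='average'`` estimates the reliability of the k-rater
    mean.
    """
    dec = anova_decompose(matrix)
    n, k = matrix.n, matrix.k
    msr, msc, mse = dec.ms_rows, dec.ms_cols, dec.ms_error
    if measure == "single":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        form = "two-way random, absolute agreement, single rater (ICC A,1)"
    elif measure == "average":
        denom = msr + (msc - mse) / n
        form = f"two-way random, absolute agreement, average of {k} raters (ICC A,{k})"
    else:
        raise ValueError(f"unknown measure {measure!r}")
    scale = max(msr, msc, mse, 1.0)
    if abs(denom) <= 1e-12 * scale:
        raise DegenerateDataError(
            "ICC undefined: no variance in the rating matrix (all cells equal)"
        )
    est = (msr - mse) / denom
    return ICCResult(estimate=float(est), form=form, decomposition=dec,
                     band=interpret_icc(float(est)))


@dataclass(frozen=True)
class PerSiteICC:
    by_site: Mapping[str, Optional[ICCResult]]  # None = insufficient pairs
    pooled: ICCResult
    n_pairs: Mapping[str, int]


def per_site_icc(sheets: Iterable[ScoreSheet], sites: Mapping[str, str],
                 raters: Sequence[str] = ("trainee", "attending"),
                 measure: str = "single") -> PerSiteICC:
    """ICC per site plus a pooled estimate over the stacked matrix.

    ``sites`` maps case_id to site. A site with fewer than 2 complete rater
    pairs is reported as insufficient (``None``), never as an estimate.
    """
    sheets = list(sheets)
    by_site: dict[str, list[ScoreSheet]] = {}
    for s in sheets:
        site = sites.get(s.case_id)
        if site is None:
            raise ValueError(f"case {s.case_id!r} has no site label")
        by_site.setdefault(site, []).append(s)
    results: dict[str, Optional[ICCResult]] = {}
    n_pairs: dict[str, int] = {}
    for site, group in sorted(by_site.items()):
        try:
            m = RatingMatrix.from_sheets(group, raters=raters)
        except ValueError:
            results[site] = None
            n_pairs[site] = 0
            logger.warning("site %s: fewer than 2 complete rater pairs — "
                           "ICC not estimated", site)
            continue
        n_pairs[site] = m.n
        results[site] = icc_absolute_agreement(m, measure=measure)
    pooled = icc_absolute_agreement(RatingMatrix.from_sheets(sheets, raters=raters),
                                    measure=measure)
    return PerSiteICC(by_site=results, pooled=pooled, n_pairs=n_pairs)


def rank_agreement(rank_a: Sequence[int], rank_b: Sequence[int],
                   tolerance: int = 2) -> float:
    """Fraction of items whose two rank positions differ by at most
    ``tolerance`` (inclusive: a difference of exactly ``tolerance`` counts
    as consistent).

    Both arguments must be permutations of 1..n aligned item-by-item.
    """
    a = np.asarray(rank_a)
    b = np.asarray(rank_b)
    if a.ndim != 1 or a.shape != b.shape:
        raise ValueError("rank vectors must be one-dimensional and equal-length")
    n = a.size
    if n == 0:
        raise ValueError("empty rank vectors")
    expected = np.arange(1, n + 1)
    for name, v in (("rank_a", a), ("rank_b", b)):
        if not np.array_equal(np.sort(v), expected):
            raise ValueError(f"{name} is not a permutation of 1..{n}")
    return float(np.mean(np.abs(a - b) <= tolerance))
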