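"""Case records and per-rater score sheets.

A :class:`CaseRecord` holds one surgical candidate's demographic, comorbidity,
disease and procedure attributes. Attribute vocabularies (category spellings,
numeric ranges) are declared by the rubric document's ``domains`` section; the
record itself is a plain container so that alternative rubric configurations
can reference the same fields with different cut-points.

A :class:`ScoreSheet` is the result of applying a rubric to one case by one
rater: 16 factor scores, three component subtotals and a total. Lower totals
indicate higher surgical priority.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Optional

COMPONENTS = ("procedure", "disease", "patient")

#: subtotal bounds implied by the component factor counts (5/4/7 factors,
#: each scored 1-5)
SUBTOTAL_BOUNDS = {
    "procedure": (5, 25),
    "disease": (4, 20),
    "patient": (7, 35),
}
TOTAL_BOUNDS = (16, 80)


@dataclass
class CaseRecord:
    """One surgical candidate awaiting scheduling.

    Optional attributes default to ``None``; scoring raises a missing-data
    error rather than imputing, so a record only needs the attributes the
    rubric in use actually references.
    """

    case_id: str
    site_id: Optional[str] = None
    age: Optional[float] = None  # years
    bmi: Optional[float] = None  # kg/m2
    parity: Optional[int] = None
    menopausal_status: Optional[str] = None  # pre | post
    race_ethnicity: Optional[str] = None
    lung_disease: Optional[str] = None
    smoking_status: Optional[str] = None
    osa_status: Optional[str] = None
    cardiovascular_disease: Optional[str] = None
    diabetes_status: Optional[str] = None
    hba1c: Optional[float] = None  # percent; required when medicated
    immunocompromised: Optional[bool] = None
    covid_status: Optional[str] = None
    expected_or_time: Optional[float] = None  # minutes
    expected_los: Optional[str] = None
    icu_need: Optional[str] = None
    least_invasive_anesthesia: Optional[str] = None
    surgical_site_approach: Optional[str] = None
    nonoperative_effectiveness: Optional[str] = None
    nonoperative_resource_use: Optional[str] = None
    delay_impact_3_6mo: Optional[str] = None
    delay_impact_gt6mo: Optional[str] = None
    indication: Optional[str] = None
    planned_procedure_class: Optional[str] = None
    acuity_tier: Optional[str] = None  # high | intermediate | low

    def __post_init__(self) -> None:
        if self.age is not None and not self.age > 0:
            raise ValueError(f"case {self.case_id!r}: age must be positive, got {self.age}")
        if self.bmi is not None and not (10 < self.bmi < 80):
            raise ValueError(f"case {self.case_id!r}: bmi must lie in (10, 80), got {self.bmi}")

    def validate(self) -> "CaseRecord":
        """Check cross-field invariants that cannot be enforced field-wise."""
        if self.diabetes_status == "medicated" and self.hba1c is None:
            raise ValueError(
                f"case {self.case_id!r}: hba1c is required when diabetes_status='medicated'"
            )
        return self

    def get(self, name: str):
        return getattr(self, name)

    def replace(self, **changes) -> "CaseRecord":
        return dataclasses.replace(self, **changes)


def case_field_names() -> list[str]:
    """Documented CSV column order for case records."""
    return [f.name for f in dataclasses.fields(CaseRecord)]


@dataclass(frozen=True)
class ScoreSheet:
    """Per-factor scores, component subtotals and total for one (case, rater)."""

    case_id: str
    rater_id: str
    rater_role: str  # trainee | attending
    factor_scores: Mapping[str, int]
    procedure_subtotal: int
    disease_subtotal: int
    patient_subtotal: int
    total: int

    def subtotal(self, component: str) -> int:
        return getattr(self, f"{component}_subtotal")

    def validate(self) -> "ScoreSheet":
        if len(self.factor_scores) != 16:
            raise ValueError(
                f"sheet ({self.case_id}, {self.rater_id}): expected 16 factor scores, "
                f"got {len(self.factor_scores)}"
            )
        for fid, s in self.factor_scores.items():
            if not (isinstance(s, (int,)) and 1 <= s <= 5):
                raise ValueError(
                    f"sheet ({self.case_id}, {self.rater_id}): factor {fid!r} score {s!r} "
                    "is not an integer in 1-5"
                )
        subtotal_sum = self.procedure_subtotal + self.disease_subtotal + self.patient_subtotal
        if self.total != subtotal_sum or self.total != sum(self.factor_scores.values()):
            raise ValueError(
                f"sheet ({self.case_id}, {self.rater_id}): total {self.total} does not equal "
                f"the sum of subtotals ({subtotal_sum}) and factor scores"
            )
        for comp, (lo, hi) in SUBTOTAL_BOUNDS.items():
            sub = self.subtotal(comp)
            if not lo <= sub <= hi:
                raise ValueError(
                    f"sheet ({self.case_id}, {self.rater_id}): {comp} subtotal {sub} "
                    f"outside [{lo}, {hi}]"
                )
        if not TOTAL_BOUNDS[0] <= self.total <= TOTAL_BOUNDS[1]:
            raise ValueError(
                f"sheet ({self.case_id}, {self.rater_id}): total {self.total} outside "
                f"[{TOTAL_BOUNDS[0]}, {TOTAL_BOUNDS[1]}]"
            )
        return self
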