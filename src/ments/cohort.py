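"""Synthetic cohort generator and rater-noise model.

Generates case records with the statistical structure of a multi-site
gynecology surgical waitlist — exact categorical marginals via
largest-remainder allocation, continuous attributes anchored at a reported
(min, median, max), and procedure/disease attributes filled from
indication- and approach-conditional clinical templates — plus paired
attending/trainee score sheets under a controllable disagreement model, so
the scoring, ranking and reliability stages are testable without any
external data.

Only the marginal distributions are calibrated; attributes are sampled
independently of one another (given the indication/approach templates),
which is a documented simplification, not a claim about any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import yaml

from .records import CaseRecord, ScoreSheet
from .rubric import Rubric, build_score_sheet, score_case

#: acuity tier implied by the surgical indication (diagnosis-driven schema)
TIER_BY_INDICATION = {
    "cancer": "high",
    "adnexal_mass": "high",
    "aub": "intermediate",
    "precancer": "intermediate",
    "prolapse_incontinence": "low",
    "contraception": "low",
    "other": "low",
}

# disease-factor templates per indication:
# (nonoperative_effectiveness, nonoperative_resource_use,
#  delay_impact_3_6mo, delay_impact_gt6mo)
_DISEASE_TEMPLATES = {
    "cancer": ("none_available", "hospitalization_or_transfusion",
               "significantly_worse", "significantly_worse"),
    "adnexal_mass": ("minimally_effective", "intermittent_treatment",
                     "worse", "significantly_worse"),
    "aub": ("mostly_effective", "frequent_escalating_care",
            "moderately_worse", "worse"),
    "precancer": ("moderately_effective", "intermittent_treatment",
                  "moderately_worse", "worse"),
    "prolapse_incontinence": ("moderately_effective", "low_occasional",
                              "slightly_worse", "moderately_worse"),
    "contraception": ("fully_effective", "minimal_none",
                      "no_change", "slightly_worse"),
    "other": ("moderately_effective", "intermittent_treatment",
              "slightly_worse", "moderately_worse"),
}

_ORDERED_DISEASE_DOMAINS = {
    "nonoperative_effectiveness": ["none_available", "minimally_effective",
                                   "moderately_effective", "mostly_effective",
                                   "fully_effective"],
    "nonoperative_resource_use": ["hospitalization_or_transfusion",
                                  "frequent_escalating_care",
                                  "intermittent_treatment", "low_occasional",
                                  "minimal_none"],
    "delay_impact_3_6mo": ["significantly_worse", "worse", "moderately_worse",
                           "slightly_worse", "no_change"],
    "delay_impact_gt6mo": ["significantly_worse", "worse", "moderately_worse",
                           "slightly_worse", "no_change"],
}


@dataclass(frozen=True)
class ContinuousAnchor:
    min: float
    median: float
    max: float
    integer: bool = False

    def __post_init__(self):
        if not self.min <= self.median <= self.max:
            raise ValueError(
                f"infeasible anchors: median {self.median} outside "
                f"[{self.min}, {self.max}]"
            )


@dataclass(frozen=True)
class CohortConfig:
    n: int
    categorical_marginals: Mapping[str, Mapping]
    continuous_anchors: Mapping[str, ContinuousAnchor]
    site_split: Mapping[str, float]
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n}")
        for attr, props in self.categorical_marginals.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"marginal proportions for {attr!r} sum to {total}, not 1"
                )

    @classmethod
    def from_mapping(cls, doc: Mapping, n: Optional[int] = None,
                     seed: Optional[int] = None) -> "CohortConfig":
        """Build a config from a parsed YAML/JSON document.

        Categorical marginals may be given as arbitrary non-negative weights
        (e.g. raw counts); they are normalized to proportions here.
        """
        marginals = {}
        for attr, weights in doc["categorical_marginals"].items():
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"negative weight in marginal for {attr!r}")
            total = float(sum(weights.values()))
            if total <= 0:
                raise ValueError(f"marginal for {attr!r} has zero total weight")
            marginals[attr] = {c: w / total for c, w in weights.items()}
        anchors = {a: ContinuousAnchor(**v)
                   for a, v in doc["continuous_anchors"].items()}
        split_raw = doc["site_split"]
        split_total = float(sum(split_raw.values()))
        split = {s: w / split_total for s, w in split_raw.items()}
        return cls(
            n=int(n if n is not None else doc["n"]),
            categorical_marginals=marginals,
            continuous_anchors=anchors,
            site_split=split,
            seed=int(seed if seed is not None else doc.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path, n: Optional[int] = None,
                  seed: Optional[int] = None) -> "CohortConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls.from_mapping(doc, n=n, seed=seed)

    @classmethod
    def default(cls, n: Optional[int] = None,
                seed: Optional[int] = None) -> "CohortConfig":
        """The packaged 392-patient three-site waitlist configuration."""
        with resources.files("ments").joinpath("data/default_cohort.yaml").open(
            "r", encoding="utf-8"
        ) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_mapping(doc, n=n, seed=seed)


def allocate_counts(n: int, proportions: Mapping) -> dict:
    """Deterministic largest-remainder apportionment of n units.

    Each category receives floor(n*p); the remaining units go to the
    categories with the largest fractional parts, ties broken by declared
    category order. Counts always sum to n.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    items = list(proportions.items())
    if any(p < 0 for _, p in items):
        raise ValueError("negative proportion")
    total = sum(p for _, p in items)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {total}, not 1")
    # the tiny epsilon absorbs float error in n*p for exact fractions like 293/392
    floors = [int(np.floor(n * p + 1e-9)) for _, p in items]
    remainders = [n * p - f for (_, p), f in zip(items, floors)]
    short = n - sum(floors)
    order = sorted(range(len(items)), key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        floors[i] += 1
    return {c: f for (c, _), f in zip(items, floors)}


def _two_piece_triangular(rng: np.random.Generator, anchor: ContinuousAnchor,
                          size: int) -> np.ndarray:
    """Sample so the population median sits exactly at the anchor median:
    a 50/50 mixture of a left triangle peaked at the median and a right
    triangle peaked at the median."""
    lo, med, hi = anchor.min, anchor.median, anchor.max
    left = rng.random(size) < 0.5
    out = np.empty(size)
    if med > lo:
        out[left] = rng.triangular(lo, med, med, size=int(left.sum()))
    else:
        out[left] = med
    if hi > med:
        out[~left] = rng.triangular(med, med, hi, size=int((~left).sum()))
    else:
        out[~left] = med
    if anchor.integer:
        out = np.clip(np.rint(out), lo, hi)
    return out


def _shuffled_column(rng: np.random.Generator, counts: Mapping) -> list:
    col: list = []
    for cat, c in counts.items():
        col.extend([cat] * c)
    rng.shuffle(col)
    return col


def _jitter_ordered(rng: np.random.Generator, value: str, categories: Sequence[str],
                    p: float = 0.25) -> str:
    """Shift an ordered category by one step (either direction) with
    probability p, clipped to the category range."""
    if rng.random() >= p:
        return value
    i = categories.index(value)
    step = 1 if rng.random() < 0.5 else -1
    return categories[min(len(categories) - 1, max(0, i + step))]


def _procedure_template(indication: str, planned: str,
                        rng: np.random.Generator) -> dict:
    if planned == "open_abdominal":
        t = dict(expected_or_time=180.0, expected_los="d2_3", icu_need="unlikely",
                 least_invasive_anesthesia="geta",
                 surgical_site_approach="open_abdominal")
        if indication == "cancer":
            t.update(expected_or_time=240.0, expected_los="gt3d",
                     icu_need="possible")
    elif planned == "mis":
        if indication == "prolapse_incontinence":
            # vaginal repair / vaginal hysterectomy
            t = dict(expected_or_time=120.0, expected_los="lt24h",
                     icu_need="very_unlikely",
                     least_invasive_anesthesia="general_lma",
                     surgical_site_approach="vaginal")
        else:
            # laparoscopic / robotic hysterectomy or adnexal surgery
            t = dict(expected_or_time=150.0, expected_los="lt24h",
                     icu_need="very_unlikely", least_invasive_anesthesia="geta",
                     surgical_site_approach="laparoscopic_robotic")
    else:  # "other": minor procedures
        if indication == "aub":
            # hysteroscopy / D&C
            t = dict(expected_or_time=30.0, expected_los="outpatient",
                     icu_need="very_unlikely",
                     least_invasive_anesthesia="general_lma",
                     surgical_site_approach="minor_external_or_intrauterine")
        elif indication == "prolapse_incontinence":
            # mid-urethral sling, periurethral procedures
            t = dict(expected_or_time=45.0, expected_los="outpatient",
                     icu_need="very_unlikely", least_invasive_anesthesia="mac",
                     surgical_site_approach="minor_external_or_intrauterine")
        elif indication == "adnexal_mass":
            t = dict(expected_or_time=90.0, expected_los="outpatient",
                     icu_need="very_unlikely", least_invasive_anesthesia="geta",
                     surgical_site_approach="laparoscopic_robotic")
        elif indication == "contraception":
            t = dict(expected_or_time=30.0, expected_los="outpatient",
                     icu_need="very_unlikely",
                     least_invasive_anesthesia="general_lma",
                     surgical_site_approach="minor_external_or_intrauterine")
        else:
            t = dict(expected_or_time=60.0, expected_los="outpatient",
                     icu_need="very_unlikely", least_invasive_anesthesia="mac",
                     surgical_site_approach="minor_external_or_intrauterine")
    t["expected_or_time"] = float(np.round(t["expected_or_time"]
                                           * rng.uniform(0.85, 1.2)))
    return t


def generate_cohort(config: CohortConfig) -> list[CaseRecord]:
    """Generate exactly ``config.n`` case records.

    Categorical attributes get exact largest-remainder marginal counts,
    independently shuffled with the seed; continuous attributes follow the
    two-piece triangular anchors; procedure and disease attributes are filled
    from indication/approach templates with small seeded jitter.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    columns = {
        attr: _shuffled_column(rng, allocate_counts(n, props))
        for attr, props in config.categorical_marginals.items()
    }
    columns["site_id"] = _shuffled_column(rng, allocate_counts(n, config.site_split))
    continuous = {
        attr: _two_piece_triangular(rng, anchor, n)
        for attr, anchor in config.continuous_anchors.items()
    }
    cases = []
    for i in range(n):
        indication = columns["indication"][i]
        planned = columns["planned_procedure_class"][i]
        proc = _procedure_template(indication, planned, rng)
        disease = dict(zip(
            ("nonoperative_effectiveness", "nonoperative_resource_use",
             "delay_impact_3_6mo", "delay_impact_gt6mo"),
            _DISEASE_TEMPLATES[indication],
        ))
        for attr in disease:
            disease[attr] = _jitter_ordered(rng, disease[attr],
                                            _ORDERED_DISEASE_DOMAINS[attr])
        diabetes = columns["diabetes_status"][i]
        hba1c = None
        if diabetes == "medicated":
            # triangular around a typical treated A1c; the tail crosses the
            # 8% threshold so both medicated rungs of the rubric occur
            hba1c = float(np.round(rng.triangular(5.8, 7.2, 12.0), 1))
        case = CaseRecord(
            case_id=f"C{i + 1:04d}",
            site_id=columns["site_id"][i],
            age=float(np.round(continuous["age"][i], 1)),
            bmi=float(np.round(continuous["bmi"][i], 1)),
            parity=int(continuous["parity"][i]),
            menopausal_status=columns["menopausal_status"][i],
            race_ethnicity=columns["race_ethnicity"][i],
            lung_disease=columns["lung_disease"][i],
            smoking_status=columns["smoking_status"][i],
            osa_status=columns["osa_status"][i],
            cardiovascular_disease=columns["cardiovascular_disease"][i],
            diabetes_status=diabetes,
            hba1c=hba1c,
            immunocompromised=bool(columns["immunocompromised"][i]),
            covid_status=columns["covid_status"][i],
            indication=indication,
            planned_procedure_class=planned,
            acuity_tier=TIER_BY_INDICATION[indication],
            **proc,
            **disease,
        )
        cases.append(case.validate())
    return cases


@dataclass(frozen=True)
class RaterNoiseModel:
    """Second-rater disagreement model.

    With probability ``disagreement_prob`` (scalar, or per-factor mapping)
    the trainee shifts each attending factor score by +/-1, clipped to 1-5.
    ``systematic_offset`` additionally moves the trainee total by a fixed
    signed amount, distributed over factors with headroom, to emulate a
    systematically harsher or softer rater.
    """

    disagreement_prob: Union[float, Mapping[str, float]] = 0.15
    systematic_offset: int = 0
    seed: Optional[int] = None

    def prob_for(self, factor_id: str) -> float:
        if isinstance(self.disagreement_prob, Mapping):
            p = float(self.disagreement_prob.get(factor_id, 0.0))
        else:
            p = float(self.disagreement_prob)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"disagreement probability {p} outside [0, 1]")
        return p


def _apply_offset(scores: dict, offset: int, rng: np.random.Generator) -> None:
    step = 1 if offset > 0 else -1
    lo, hi = (1, 5)
    for _ in range(abs(offset)):
        movable = [f for f, s in scores.items()
                   if (s < hi if step > 0 else s > lo)]
        if not movable:
            break
        f = movable[rng.integers(len(movable))]
        scores[f] += step


def simulate_rater_pair(rubric: Rubric, cases: Iterable[CaseRecord],
                        noise: RaterNoiseModel
                        ) -> tuple[list[ScoreSheet], list[ScoreSheet]]:
    """Score every case twice: deterministically (attending) and with the
    noise model applied (trainee). Returns (attending, trainee) sheet lists
    in case order; all sheet invariants are preserved."""
    rng = np.random.default_rng(noise.seed)
    attending, trainee = [], []
    for case in cases:
        sheet = score_case(rubric, case, rater_id="attending",
                           rater_role="attending")
        attending.append(sheet)
        fs = dict(sheet.factor_scores)
        for fid in fs:
            if rng.random() < noise.prob_for(fid):
                step = 1 if rng.random() < 0.5 else -1
                fs[fid] = min(5, max(1, fs[fid] + step))
        if noise.systematic_offset:
            _apply_offset(fs, noise.systematic_offset, rng)
        trainee.append(build_score_sheet(rubric, case.case_id, "trainee",
                                         "trainee", fs))
    return attending, trainee
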