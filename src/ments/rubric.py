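"""Scoring rubric: definition, validation and application to case records.

The modified MeNTS (Medically Necessary Time-Sensitive) instrument scores a
surgical candidate on 16 factors grouped into three components — Procedure
(5 factors), Disease (4) and Patient (7). Each factor takes an integer level
from 1 (strongest argument to operate promptly / lowest perioperative risk)
to 5 (strongest argument to defer / highest risk), so totals span 16-80 and
lower totals mean higher surgical priority.

The rubric ships as an editable YAML document: every cut-point (operating
time bands, BMI classes, the HbA1c threshold, the anesthesia-invasiveness
ladder) is configuration, not code. A factor declares its 5 levels in one of
two forms:

``levels``
    each level carries a ``when`` list of clauses; a clause is a mapping from
    case attribute to a condition (``in`` for categorical domains, any of
    ``ge``/``gt``/``le``/``lt`` for numeric ones). A level matches when any
    of its clauses matches (OR of ANDs). A level may instead be marked
    ``reserved`` — a documented rung that no combination of the declared
    attributes can reach (e.g. a gradation the record schema cannot resolve).

``ordinal_max``
    the factor score is the maximum over several single-attribute ladders,
    e.g. the lung-disease factor combines the asthma/COPD severity ladder
    with smoking status and obstructive-sleep-apnea control.

Validation proves, by brute-force sweep over the declared attribute domains,
that every attribute combination matches exactly one level, and that scores
1 and 5 are both attainable for every factor (so the instrument's total
really spans 16-80).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import MissingAttributeError, RubricValidationError, ScoringError
from .records import COMPONENTS, CaseRecord, ScoreSheet

COMPONENT_FACTOR_COUNTS = {"procedure": 5, "disease": 4, "patient": 7}

_NUMERIC_OPS = ("ge", "gt", "le", "lt")


@dataclass(frozen=True)
class AttributeDomain:
    """Declared value domain of one case attribute."""

    name: str
    kind: str  # "numeric" | "ordered"
    categories: tuple = ()
    lo: float | None = None
    hi: float | None = None
    unit: str = ""

    def representative_values(self, constants: Iterable[float] = ()) -> list:
        """Finite set of probe values that distinguishes every elementary
        region the given cut-point constants can carve out of the domain.

        For ordered (categorical) domains this is the category list itself;
        for numeric domains it is every in-range cut-point plus the midpoint
        of each gap between consecutive cut-points and the domain endpoints.
        """
        if self.kind == "ordered":
            return list(self.categories)
        pts = sorted({float(c) for c in constants if self.lo <= c <= self.hi}
                     | {float(self.lo), float(self.hi)})
        reps: list[float] = []
        for a, b in zip(pts, pts[1:]):
            reps.append(a)
            reps.append((a + b) / 2.0)
        reps.append(pts[-1])
        return reps


def _condition_matches(cond: Mapping, value) -> bool:
    if "in" in cond:
        return value in cond["in"]
    ok = True
    if "ge" in cond:
        ok = ok and value >= cond["ge"]
    if "gt" in cond:
        ok = ok and value > cond["gt"]
    if "le" in cond:
        ok = ok and value <= cond["le"]
    if "lt" in cond:
        ok = ok and value < cond["lt"]
    return ok


@dataclass(frozen=True)
class Level:
    """One rung of a factor: a score plus the criterion that selects it."""

    score: int
    label: str = ""
    clauses: tuple = ()  # tuple of {attr: condition} mappings, OR-ed together
    reserved: bool = False

    def matches(self, values: Mapping) -> tuple[bool, set]:
        """Return (matched, missing-attributes-encountered)."""
        missing: set[str] = set()
        if self.reserved:
            return False, missing
        for clause in self.clauses:
            clause_ok = True
            for attr, cond in clause.items():
                v = values.get(attr)
                if v is None:
                    missing.add(attr)
                    clause_ok = False
                    break
                if not _condition_matches(cond, v):
                    clause_ok = False
                    break
            if clause_ok:
                return True, missing
        return False, missing


@dataclass(frozen=True)
class FactorDefinition:
    factor_id: str
    component: str
    label: str
    kind: str = "levels"  # "levels" | "ordinal_max"
    levels: tuple = ()
    ladders: Mapping[str, Mapping] = field(default_factory=dict)

    def referenced_attributes(self) -> tuple:
        if self.kind == "ordinal_max":
            return tuple(self.ladders)
        attrs: list[str] = []
        for lv in self.levels:
            for clause in lv.clauses:
                for a in clause:
                    if a not in attrs:
                        attrs.append(a)
        return tuple(attrs)

    def numeric_constants(self) -> dict:
        """Cut-point constants per attribute, for domain discretization."""
        consts: dict[str, set] = {}
        for lv in self.levels:
            for clause in lv.clauses:
                for attr, cond in clause.items():
                    for op in _NUMERIC_OPS:
                        if op in cond:
                            consts.setdefault(attr, set()).add(float(cond[op]))
        return consts

    def score(self, case: CaseRecord) -> int:
        """Score one case on this factor; raises on missing data."""
        values = {a: case.get(a) for a in self.referenced_attributes()}
        return self.score_values(values, case_id=case.case_id)

    def score_values(self, values: Mapping, case_id: str = "?") -> int:
        if self.kind == "ordinal_max":
            missing = [a for a in self.ladders if values.get(a) is None]
            if missing:
                raise MissingAttributeError(
                    f"case {case_id!r}, factor {self.factor_id!r}: "
                    f"missing attribute(s) {missing}"
                )
            return max(ladder[values[a]] for a, ladder in self.ladders.items())
        hits = []
        missing: set[str] = set()
        for lv in self.levels:
            ok, miss = lv.matches(values)
            missing |= miss
            if ok:
                hits.append(lv)
        if len(hits) == 1:
            return hits[0].score
        if not hits and missing:
            raise MissingAttributeError(
                f"case {case_id!r}, factor {self.factor_id!r}: "
                f"missing attribute(s) {sorted(missing)}"
            )
        kind = "no level" if not hits else f"levels {[h.score for h in hits]}"
        raise ScoringError(
            f"case {case_id!r}, factor {self.factor_id!r}: {kind} matched "
            f"attribute values {dict(values)!r}"
        )


@dataclass(frozen=True)
class Rubric:
    name: str
    version: str
    factors: tuple
    domains: Mapping[str, AttributeDomain]

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def min_total(self) -> int:
        return self.n_factors  # every factor attains score 1 (validated)

    @property
    def max_total(self) -> int:
        return 5 * self.n_factors  # every factor attains score 5 (validated)

    def factor(self, factor_id: str) -> FactorDefinition:
        for f in self.factors:
            if f.factor_id == factor_id:
                return f
        raise KeyError(factor_id)

    def factors_by_component(self, component: str) -> list:
        return [f for f in self.factors if f.component == component]

    def factor_grid(self, factor: FactorDefinition) -> dict:
        """Probe values per referenced attribute; the product of these lists
        covers every elementary region of the factor's attribute domain."""
        consts = factor.numeric_constants() if factor.kind == "levels" else {}
        grid = {}
        for attr in factor.referenced_attributes():
            dom = self.domains.get(attr)
            if dom is None:
                raise RubricValidationError(
                    f"factor {factor.factor_id!r} references attribute {attr!r} "
                    "with no declared domain"
                )
            grid[attr] = dom.representative_values(consts.get(attr, ()))
        return grid

    # ---------------------------------------------------------------- checks

    def validate(self) -> "Rubric":
        counts = Counter(f.component for f in self.factors)
        for comp in COMPONENTS:
            if counts.get(comp, 0) != COMPONENT_FACTOR_COUNTS[comp]:
                raise RubricValidationError(
                    f"rubric {self.name!r}: component {comp!r} has "
                    f"{counts.get(comp, 0)} factors, expected "
                    f"{COMPONENT_FACTOR_COUNTS[comp]}"
                )
        ids = [f.factor_id for f in self.factors]
        if len(set(ids)) != len(ids):
            raise RubricValidationError(f"rubric {self.name!r}: duplicate factor ids")
        for f in self.factors:
            if f.component not in COMPONENTS:
                raise RubricValidationError(
                    f"factor {f.factor_id!r}: unknown component {f.component!r}"
                )
            if f.kind == "ordinal_max":
                self._validate_ordinal_max(f)
            else:
                self._validate_levels(f)
        return self

    def _validate_ordinal_max(self, f: FactorDefinition) -> None:
        if not f.ladders:
            raise RubricValidationError(f"factor {f.factor_id!r}: no ladders declared")
        for attr, ladder in f.ladders.items():
            dom = self.domains.get(attr)
            if dom is None or dom.kind != "ordered":
                raise RubricValidationError(
                    f"factor {f.factor_id!r}: ladder attribute {attr!r} must have "
                    "an ordered domain"
                )
            if set(ladder) != set(dom.categories):
                missing = set(dom.categories) - set(ladder)
                extra = set(ladder) - set(dom.categories)
                raise RubricValidationError(
                    f"factor {f.factor_id!r}, ladder {attr!r}: does not cover the "
                    f"domain (missing {sorted(map(str, missing))}, "
                    f"extraneous {sorted(map(str, extra))})"
                )
            vals = [ladder[c] for c in dom.categories]
            if any(not (isinstance(v, int) and 1 <= v <= 5) for v in vals):
                raise RubricValidationError(
                    f"factor {f.factor_id!r}, ladder {attr!r}: scores must be "
                    "integers in 1-5"
                )
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise RubricValidationError(
                    f"factor {f.factor_id!r}, ladder {attr!r}: scores must be "
                    "non-decreasing along the declared category order"
                )
        min_attainable = max(min(l.values()) for l in f.ladders.values())
        max_attainable = max(max(l.values()) for l in f.ladders.values())
        if min_attainable != 1 or max_attainable != 5:
            raise RubricValidationError(
                f"factor {f.factor_id!r}: attainable scores span "
                f"[{min_attainable}, {max_attainable}], expected [1, 5]"
            )

    def _validate_levels(self, f: FactorDefinition) -> None:
        if len(f.levels) != 5:
            raise RubricValidationError(
                f"factor {f.factor_id!r}: has {len(f.levels)} levels, expected 5"
            )
        scores = sorted(lv.score for lv in f.levels)
        if scores != [1, 2, 3, 4, 5]:
            raise RubricValidationError(
                f"factor {f.factor_id!r}: level scores {scores} are not "
                "exactly {{1,2,3,4,5}}"
            )
        grid = self.factor_grid(f)
        attrs = list(grid)
        reachable: set[int] = set()
        for combo in itertools.product(*(grid[a] for a in attrs)):
            values = dict(zip(attrs, combo))
            hits = [lv for lv in f.levels if lv.matches(values)[0]]
            if not hits:
                raise RubricValidationError(
                    f"factor {f.factor_id!r}: criteria are not exhaustive — no level "
                    f"covers {values!r}"
                )
            if len(hits) > 1:
                raise RubricValidationError(
                    f"factor {f.factor_id!r}: criteria overlap — levels "
                    f"{[h.score for h in hits]} all match {values!r}"
                )
            reachable.add(hits[0].score)
        for extreme in (1, 5):
            if extreme not in reachable:
                raise RubricValidationError(
                    f"factor {f.factor_id!r}: score {extreme} is unreachable, so the "
                    "instrument's total range would not be attained"
                )


# -------------------------------------------------------------------- loading


def _parse_domain(name: str, raw: Mapping) -> AttributeDomain:
    kind = raw.get("type")
    if kind == "ordered":
        cats = tuple(raw.get("categories", ()))
        if len(cats) < 2:
            raise RubricValidationError(f"domain {name!r}: needs >= 2 categories")
        return AttributeDomain(name, "ordered", categories=cats, unit=raw.get("unit", ""))
    if kind == "numeric":
        lo, hi = raw.get("min"), raw.get("max")
        if lo is None or hi is None or not lo < hi:
            raise RubricValidationError(f"domain {name!r}: needs min < max")
        return AttributeDomain(name, "numeric", lo=float(lo), hi=float(hi),
                               unit=raw.get("unit", ""))
    raise RubricValidationError(f"domain {name!r}: unknown type {kind!r}")


def _parse_condition(attr: str, raw) -> Mapping:
    if isinstance(raw, Mapping):
        unknown = set(raw) - set(_NUMERIC_OPS) - {"in"}
        if unknown:
            raise RubricValidationError(
                f"condition on {attr!r}: unknown operator(s) {sorted(unknown)}"
            )
        if "in" in raw and not isinstance(raw["in"], list):
            return {"in": [raw["in"]]}
        return dict(raw)
    if isinstance(raw, list):
        return {"in": list(raw)}
    return {"in": [raw]}  # bare scalar shorthand


def _parse_factor(raw: Mapping) -> FactorDefinition:
    try:
        fid = raw["id"]
        component = raw["component"]
        label = raw.get("label", fid)
    except (KeyError, TypeError) as exc:
        raise RubricValidationError(f"malformed factor entry {raw!r}") from exc
    kind = raw.get("kind", "levels")
    if kind == "ordinal_max":
        ladders = {a: dict(l) for a, l in raw.get("ladders", {}).items()}
        return FactorDefinition(fid, component, label, kind="ordinal_max",
                                ladders=ladders)
    levels = []
    for lraw in raw.get("levels", ()):
        score = lraw.get("score")
        if not isinstance(score, int):
            raise RubricValidationError(
                f"factor {fid!r}: level without an integer score: {lraw!r}"
            )
        if lraw.get("reserved"):
            levels.append(Level(score, label=lraw.get("label", ""), reserved=True))
            continue
        clauses = tuple(
            {a: _parse_condition(a, c) for a, c in clause.items()}
            for clause in lraw.get("when", ())
        )
        if not clauses:
            raise RubricValidationError(
                f"factor {fid!r}, level {score}: no 'when' clauses and not reserved"
            )
        levels.append(Level(score, label=lraw.get("label", ""), clauses=clauses))
    return FactorDefinition(fid, component, label, kind="levels", levels=tuple(levels))


def load_rubric(source) -> Rubric:
    """Load and validate a rubric from a YAML/JSON document.

    ``source`` may be a path, a YAML string starting with a mapping already
    parsed (a ``dict``), or an open file object.
    """
    if isinstance(source, Mapping):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        doc = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
    if not isinstance(doc, Mapping):
        raise RubricValidationError("rubric document is not a mapping")
    try:
        name = doc["name"]
        version = str(doc["version"])
        raw_factors = doc["factors"]
        raw_domains = doc["domains"]
    except KeyError as exc:
        raise RubricValidationError(f"rubric document missing key {exc}") from exc
    domains = {n: _parse_domain(n, d) for n, d in raw_domains.items()}
    factors = tuple(_parse_factor(f) for f in raw_factors)
    return Rubric(name=name, version=version, factors=factors, domains=domains).validate()


def default_rubric() -> Rubric:
    """The packaged modified-MeNTS rubric (reconstructed cut-points)."""
    with resources.files("ments").joinpath("data/modified_ments.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        return load_rubric(fh)


# -------------------------------------------------------------------- scoring


def score_factor(factor: FactorDefinition, case: CaseRecord) -> int:
    """Score one factor for one case (1-5); raises on missing attributes."""
    return factor.score(case)


def build_score_sheet(rubric: Rubric, case_id: str, rater_id: str, rater_role: str,
                      factor_scores: Mapping[str, int]) -> ScoreSheet:
    """Assemble a validated ScoreSheet from per-factor scores."""
    subtotals = {comp: 0 for comp in COMPONENTS}
    for f in rubric.factors:
        if f.factor_id not in factor_scores:
            raise ScoringError(f"sheet ({case_id}, {rater_id}): missing factor "
                               f"{f.factor_id!r}")
        subtotals[f.component] += int(factor_scores[f.factor_id])
    sheet = ScoreSheet(
        case_id=case_id,
        rater_id=rater_id,
        rater_role=rater_role,
        factor_scores={f.factor_id: int(factor_scores[f.factor_id])
                       for f in rubric.factors},
        procedure_subtotal=subtotals["procedure"],
        disease_subtotal=subtotals["disease"],
        patient_subtotal=subtotals["patient"],
        total=sum(subtotals.values()),
    )
    return sheet.validate()


def score_case(rubric: Rubric, case: CaseRecord, rater_id: str = "rater",
               rater_role: str = "attending") -> ScoreSheet:
    """Apply the full rubric to one case.

    Deterministic given (rubric, case); missing attributes raise
    :class:`~ments.errors.MissingAttributeError` with factor context.
    """
    scores = {f.factor_id: f.score(case) for f in rubric.factors}
    return build_score_sheet(rubric, case.case_id, rater_id, rater_role, scores)
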