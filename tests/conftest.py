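import pytest

from ments import CaseRecord, default_rubric

# A complete mid-range case: 46-year-old premenopausal never-smoker without
# comorbidities, COVID status unknown, scheduled for hysteroscopy for
# abnormal uterine bleeding.
BASE_CASE = dict(
    case_id="W1",
    site_id="HUMC",
    age=46.0,
    bmi=30.7,
    parity=2,
    menopausal_status="pre",
    race_ethnicity="latina",
    lung_disease="none",
    smoking_status="never",
    osa_status="none",
    cardiovascular_disease="none",
    diabetes_status="none",
    hba1c=None,
    immunocompromised=False,
    covid_status="unknown",
    expected_or_time=30.0,
    expected_los="outpatient",
    icu_need="very_unlikely",
    least_invasive_anesthesia="general_lma",
    surgical_site_approach="minor_external_or_intrauterine",
    nonoperative_effectiveness="mostly_effective",
    nonoperative_resource_use="low_occasional",
    delay_impact_3_6mo="no_change",
    delay_impact_gt6mo="moderately_worse",
    indication="aub",
    planned_procedure_class="other",
    acuity_tier="intermediate",
)

# every factor at its lowest rung: the most urgent, lowest-risk case possible
MIN_CASE = dict(
    BASE_CASE,
    case_id="MIN",
    age=19.0,
    bmi=22.0,
    covid_status="negative",
    expected_or_time=20.0,
    least_invasive_anesthesia="local",
    nonoperative_effectiveness="none_available",
    nonoperative_resource_use="hospitalization_or_transfusion",
    delay_impact_3_6mo="significantly_worse",
    delay_impact_gt6mo="significantly_worse",
)

# every factor at its highest rung: the strongest argument to defer
MAX_CASE = dict(
    BASE_CASE,
    case_id="MAX",
    age=70.0,
    bmi=55.0,
    lung_disease="copd_severe",
    cardiovascular_disease="multiple_uncontrolled_cv",
    diabetes_status="medicated",
    hba1c=9.5,
    immunocompromised=True,
    covid_status="positive",
    expected_or_time=300.0,
    expected_los="gt3d",
    icu_need="expected",
    least_invasive_anesthesia="geta",
    surgical_site_approach="airway_upper_gi",
    nonoperative_effectiveness="fully_effective",
    nonoperative_resource_use="minimal_none",
    delay_impact_3_6mo="no_change",
    delay_impact_gt6mo="no_change",
)


def make_case(**overrides) -> CaseRecord:
    return CaseRecord(**{**BASE_CASE, **overrides})


@pytest.fixture(scope="session")
def rubric():
    return default_rubric()


@pytest.fixture
def base_case():
    return make_case()


@pytest.fixture
def min_case():
    return CaseRecord(**MIN_CASE)


@pytest.fixture
def max_case():
    return CaseRecord(**MAX_CASE)
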