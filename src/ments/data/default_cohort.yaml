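# Default synthetic-cohort configuration: a 392-patient gynecology surgical
# waitlist across three Los Angeles County safety-net hospitals.
#
# Categorical marginals are given as weights (here: patient counts out of
# 392); the loader normalizes them to proportions, and largest-remainder
# allocation reproduces the counts exactly at n=392. Attributes not reported
# at this granularity (the severity split within "any lung disease" or "any
# cardiovascular disease", smoking, OSA) use plausible clinical splits that
# preserve the reported any-disease totals. The six patients whose COVID-19
# status was not recorded as unknown are assigned negative.
#
# Continuous attributes are reported as median and range; the generator
# samples a two-piece triangular distribution anchored at (min, median, max).
n: 392
seed: 2020
site_split: {HUMC: 1, OVMC: 1, LACUSC: 1}
categorical_marginals:
  race_ethnicity:
    {latina: 293, black: 19, asian_pi: 15, white: 12, other: 53}
  menopausal_status: {pre: 263, post: 129}
  lung_disease:
    # 43/392 with any lung disease
    {none: 349, asthma_controlled: 25, asthma_uncontrolled: 10,
     copd_moderate: 6, copd_severe: 2}
  smoking_status: {never: 255, former: 90, current: 47}
  osa_status: {none: 333, treated: 39, untreated: 20}
  cardiovascular_disease:
    # 205/392 with any cardiovascular disease
    {none: 187, controlled_htn: 150, uncontrolled_htn_or_single_cv: 40,
     multiple_cv_or_chf_cad: 12, multiple_uncontrolled_cv: 3}
  diabetes_status:
    # 54/392 with diabetes
    {none: 338, diet_controlled: 22, medicated: 32}
  immunocompromised: {false: 373, true: 19}
  covid_status: {negative: 6, unknown: 386, positive: 0}
  indication:
    {aub: 130, prolapse_incontinence: 77, adnexal_mass: 56, precancer: 29,
     contraception: 26, cancer: 7, other: 67}
  planned_procedure_class: {open_abdominal: 56, mis: 215, other: 121}
continuous_anchors:
  age: {min: 20, median: 46, max: 86}
  bmi: {min: 17.8, median: 30.7, max: 67.3}
  parity: {min: 0, median: 2, max: 8, integer: true}
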