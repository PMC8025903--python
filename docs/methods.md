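# Methods

## The instrument

The scoring engine implements a 16-factor adaptation of the MeNTS
(Medically Necessary Time-Sensitive) surgical prioritization worksheet for
gynecologic services: 5 Procedure, 4 Disease and 7 Patient factors, each an
integer 1–5, giving totals in [16, 80]. Orientation is fixed throughout the
package: 1 argues to operate promptly (low perioperative risk, high
time-sensitivity), 5 argues to defer, so lower totals rank first. The two
delay-impact factors (3–6 months; more than 6 months) are deliberately
separate factors, reflecting the stratification of outcome impact by delay
horizon.

### Reconstructed cut-points

The published worksheet figure is not available cell-by-cell, so the default
rubric reconstructs level boundaries from the instrument's stated anchors
and ships them as data (`data/modified_ments.yaml`), never as code:

- operating-time bands ≤30 / 31–60 / 61–120 / 121–180 / >180 min; length of
  stay outpatient / <24 h / 24–48 h / 2–3 d / >3 d; five ICU-need
  probability bands;
- the anesthesia-invasiveness ladder local < MAC < regional < general-LMA <
  GETA, and a surgical-site ladder whose first rung is minor external pelvic
  or minimally-invasive-to-uterus surgery (hysteroscopy, D&C), rising
  through vaginal and laparoscopic/robotic to open abdominal, with
  aerosolizing airway/upper-GI sites on the top rung;
- BMI at the established obesity classes <30 / 30–34.9 / 35–39.9 / 40–49.9 /
  ≥50 kg/m²; age bands <20 / 20–40 / 41–50 / 51–65 / >65 years;
- diabetes anchored at the HbA1c > 8 % threshold: none → 1, diet-controlled
  → 2, medicated with HbA1c ≤ 8 → 3, medicated with HbA1c > 8 → 5. Level 4
  is declared `reserved` (a gradation — poor control without end-organ
  disease — that the record schema cannot resolve); reserved rungs are legal
  in the document format and validated as intentionally unreachable.
- the lung factor is an `ordinal_max` over three ladders — asthma/COPD
  severity, smoking status, OSA control — so the worst of the three drives
  the score; COVID status maps negative/unknown/positive to 1/3/5 (the
  unknown middle avoids biasing totals in populations where testing data are
  sparse); immunocompromise is binary (1 or 5).

### Validation

`load_rubric` proves three properties per factor before any scoring:
exactly five levels using scores {1,…,5} once each (reserved rungs
permitted); criteria exhaustive and mutually exclusive, by enumerating the
product of attribute domains — categorical domains directly, numeric
domains discretized at every declared cut-point plus the midpoint of each
gap, which distinguishes all elementary intervals the conditions can carve;
and attainability of both extremes, so a fully-benign and a fully-deferrable
case really score 16 and 80. Missing attributes raise an error naming the
factor and attribute; the engine never imputes, because imputation policy
belongs to the caller.

## Ranking and summaries

Queues sort ascending by total. Ties break by disease subtotal (ascending —
the more time-sensitive disease goes first) and then case id; the choice is
a package convention whose only requirement is determinism. Medians use the
midpoint of the two central values for even n. The tier crosswalk reports
per-tier medians and a monotonicity flag (median(high) ≤
median(intermediate) ≤ median(low)), the direction expected when the score
agrees with a diagnosis-driven acuity schema. Multi-rater inputs are
collapsed before ranking by an explicit policy: `attending` (default, keep
the attending sheet) or `mean`.

## Reliability model

Ratings form a fully crossed two-way layout without replication: n cases ×
k raters, both treated as random samples. `anova_decompose` computes the
standard between-subject, between-rater and residual mean squares;
`icc_absolute_agreement` forms the single-rater absolute-agreement ICC —
ICC(A,1), equivalently ICC(2,1) —

    ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E)),

with the k-rater average form ICC(A,k) behind `measure="average"`. The
single-rater form is the default because in deployment one clinician scores
a case. Absolute agreement (not consistency) is used because a systematic
shift between raters changes the queue, and penalizing it is the
conservative choice. A fully constant matrix raises an explicit
degenerate-data error rather than returning 0. Interpretation uses the
Cicchetti bands poor < 0.40, fair 0.40–0.59, good 0.60–0.74, excellent
≥ 0.75. Per-site analysis drops cases missing either rater (logged), reports
sites with fewer than two complete pairs as insufficient rather than
estimating, and pools by stacking all complete pairs into one ANOVA. No
confidence intervals or tests are computed. Rank consistency is the fraction
of cases whose two rank positions differ by at most a tolerance
(default 2, inclusive).

## Synthetic cohort

The default configuration (`data/default_cohort.yaml`) encodes a 392-patient
gynecology waitlist across three hospitals. Categorical attributes use
largest-remainder apportionment — floor(n·p) per category, remaining units
by descending fractional part, ties by declared order — so marginal counts
are exact for every seed; each attribute's labels are then shuffled
independently. Where a source marginal reports only "any disease" (lung,
cardiovascular, diabetes), the severity split within the diseased group, and
the smoking/OSA marginals, are plausible clinical choices that preserve the
any-disease totals; they are stated in the YAML and are configuration, not
code. The six patients without a recorded unknown COVID status are assigned
negative.

Continuous attributes (age, BMI, parity) are drawn from a two-piece
triangular distribution — a 50/50 mixture of a left triangle peaked at the
anchor median and a right triangle peaked there too — because the source
statistics are exactly (min, median, max); the population median then equals
the anchor, and all draws respect the range. Parity is rounded to integers.
Medicated diabetics draw HbA1c from a triangular (5.8, 7.2, 12.0) so both
medicated rungs of the diabetes factor occur.

Procedure and disease attributes are filled from indication- and
approach-conditional templates (open hysterectomy, MIS hysterectomy,
vaginal prolapse repair, hysteroscopy, diagnostic laparoscopy, minor
procedures…), with ±1-step seeded jitter on the four ordered disease
attributes and ±(−15 %, +20 %) jitter on operative time. Acuity tiers derive
from the indication (cancer and adnexal mass high; bleeding and precancer
intermediate; prolapse, contraception and other low). **Only marginals are
calibrated**: attributes are jointly independent given the templates, true
comorbidity correlations are absent, and the score distribution the
generator induces is an emulation — tests passing on it demonstrate the
pipeline's correctness, not properties of any real cohort, and the package
deliberately does not try to reproduce empirical score medians or ICC
values observed in clinical use.

The rater-noise model perturbs each attending factor score by ±1 with a
per-factor disagreement probability (clipped to 1–5) and can add a
systematic offset to the trainee total, distributed over factors with
headroom. Clipping at the scale ends halves the shift variance there
(variance p/2 − p²/4 versus p in the interior) and introduces a small bias
toward the middle; the tests account for both exactly when predicting the
expected total difference and the theoretical ICC of a simulated pair.

## Numerical and interface choices

- Deterministic everything: a single integer seed fixes the cohort, the
  noise, and all CLI outputs byte-for-byte (metadata header aside).
- CSV dialect RFC 4180, UTF-8, "." decimal; files carry `#` metadata
  comment lines (tool version, rubric version, seed); writes are atomic
  (temp file + rename) so failures never leave partial outputs.
- Score-sheet files are re-verified on read: totals must equal the sum of
  the 16 factor columns.
- Problem sizes in the test suite (cohorts of 392, reliability simulations
  at n=500–1000 with 50 seeds, 200 random oracle matrices) keep the whole
  suite under ~10 s while leaving the estimators' sampling error well inside
  the asserted tolerances.

## Known limitations

- The reconstructed cut-points are faithful to the instrument's stated
  anchors but not guaranteed cell-identical to the published worksheet;
  users with the worksheet can edit the YAML to match.
- Joint independence of patient attributes understates real-world
  comorbidity clustering; ICCs measured on synthetic pairs reflect the noise
  model, not clinician behaviour.
- The component structure (5/4/7 factors, totals 16–80) is enforced;
  documents with other structures are rejected by design, so encoding the
  original 21-factor instrument requires relaxing
  `COMPONENT_FACTOR_COUNTS`, which is out of scope here.
- No confidence intervals on ICC, and no schedule optimization downstream of
  the queue: the tool scores and ranks, it does not decide.
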