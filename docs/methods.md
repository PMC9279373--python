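# Methods

This note documents the models and procedures implemented in `fastlabel`,
the defaults and why they were chosen, and what the synthetic-data tests do
and do not establish about real EMR data.

## The verification problem

Outpatient "fasting" glucose (AC, ante cibum) is verified in two
independent ways:

* **Ontological fasting** (`glucose_conditioning`): the record *claims* to
  be fasting — an outpatient AC order, a valid numeric value, no
  point-of-care annotations, the first draw of the patient's day.
* **Theoretical fasting** (`fasting_labeler`): the value is *biologically
  consistent* with fasting, using the HbA1c-derived estimated average
  glucose (eAG) as a per-patient upper limit.

The gap between the two quantifies non-adherence to fasting instructions;
the ineffective-glucose-measurement (IGM) statistic expresses its clinical
cost.

## Conditioning rules and the exclusion ledger

Rules run in a fixed order and the first matching rule supplies the reason
code: value validity (nonnumeric, > 1000 mg/dL strict, exactly zero;
negative parses count as nonnumeric), missing collection timestamp, care
setting, PC/random order label, nonfasting annotation tags
(case-insensitive exact tags against a configurable vocabulary — the
labels are discrete in laboratory systems, so no free-text mining), and
same-day repeats. For repeats the *first* draw of the calendar day is
retained and later draws are excluded, because a later draw follows
possible food intake; ties on the timestamp break deterministically by
record id. The ledger has exactly one row per input record, so
`|input| = |retained| + |excluded|` always holds and a second pass is a
no-op.

## The labeling criteria

eAG = 28.7·A1c − 46.7 mg/dL (the standard linear regression of mean
glucose on HbA1c; both coefficients configurable for other unit systems).
The three criteria are strict (<) everywhere, so a value exactly at a
threshold is nonfasting. Decisions taken where the rule set is open:

* The non-DM HbA1c band "5.5–6.4 %" is implemented as 5.5 ≤ A1c < 6.5 so
  no gap exists between 6.4 and 6.5.
* The 1-SD term of criterion 2 (`sd_reference`) defaults to the sample SD
  (n−1) of the cohort's non-DM ontological glucose values, matching the
  stratum the criterion applies to; a fixed value can be supplied instead
  (`sd_mode="fixed"`), and the value used is always reported.
* Non-DM patients with A1c ≥ 6.5 % fall outside the three bands
  (biochemically diabetic but not yet diagnosed). They get the criterion-3
  rule form (g < eAG), which is the eAG upper-limit argument independent of
  diagnosis status, and carry a distinct audit flag
  (`offband_nondm_high_a1c`).
* DM status at sampling = recorded diagnosis/medication onset on or before
  the collection date.
* Samples without a same-day HbA1c are *unlabelable*, never nonfasting.

## Synthetic EMR generator

The generator (`synthetic_emr`) emulates the structure downstream stages
assume, with ground truth the real setting lacks:

* **Population.** DM prevalence 0.292; age ~ Normal(57, 15) clipped to
  [20, 95]; 53 % male; comorbidity and medication onsets at plausible
  outpatient rates (hypertension 40 %, CAD 15 %, stroke 10 %, statins
  25 %). One hospital; homes scattered with an exponential distance decay
  (mean 12 km), which makes the distance covariate realistically
  right-skewed.
* **HbA1c.** Per sample, Normal(5.86, 0.98) % for non-DM and
  Normal(7.59, 1.42) % for DM (the fasting-cohort moments of the study
  population this generator emulates), truncated at 3.5 %.
* **Adherence.** Whether a draw is truly fasted follows a logistic model
  whose coefficients are log odds of a *nonfasting* draw, defaulting to a
  published odds-ratio structure (age 1.05 per 5 y, male 1.16, distance
  0.998 per 10 km, afternoon/evening sampling protective, clinical
  divisions ≈ 2× the health-check reference). DM (0.70) and concomitant
  lipid testing (0.78) use the unadjusted odds ratios: the corresponding
  fully-adjusted estimates are conditioned on glucose itself, which is an
  *outcome* of fasting in the generative direction, and adopting them
  would produce implausible marginal fasting rates. The intercept (−1.1)
  puts the marginal nonfasting share near one half, matching the roughly
  1:1 fasting/nonfasting mix seen in labeled outpatient cohorts.
* **Glucose.** Fasting draws ~ Normal(eAG − 25, 15), nonfasting
  ~ Normal(eAG + 30, 35), both truncated at 40 mg/dL and rounded to
  integers. The offsets reproduce the canonical bimodal picture — fasting
  non-DM peak just under 100 mg/dL, nonfasting DM peak above 126 mg/dL —
  and the printed stratum means, without asserting anything about true
  postprandial dynamics (no published distributional form exists; the
  offset-Normal is a declared stand-in).
* **Noise.** Independent per-record corruption at configurable rates:
  order label flipped to PC/random (2 %), nonfasting annotations (2 %),
  same-day duplicate draws two hours later redrawn from the nonfasting
  model (1 %), nonnumeric values (0.5 %), zeros (0.3 %), values > 1000
  (0.2 %), non-outpatient settings (5 %).
* **Determinism.** One `numpy` Generator seeded from `seed`; fixed seed ⇒
  byte-identical tables. The pre-procedure subset generator derives an
  independent stream from `(seed, 0xFA57)`.

What the generator does **not** emulate: within-patient correlation of
adherence over visits, seasonal/secular trends, assay drift, informative
missingness of HbA1c, multi-site care, or realistic joint distributions
beyond the stated moments. Passing tests therefore demonstrate the
*pipeline's correctness and internal consistency*, not clinical
performance on any real cohort; the restricted-data AUROCs and cohort
tables of the motivating setting are not reproducible here and are not
claimed.

A consequence of the cohort-derived `sd_reference` (≈ 46 mg/dL on default
synthetic cohorts) is that criterion 2 is deliberately conservative: many
truly fasted non-DM draws in the 5.5–6.5 % band sit above eAG − SD, so the
labeler's one-sided misclassification of true fasting samples is ~28 % on
the default synthetic pre-procedure subset. With a tighter fixed
`sd_reference` and a well-separated generator the rate goes to ~0 (tested);
the rate on real data depends on the true fasting spread, which the
generator does not claim to know.

## Modeling and evaluation

* **Dataset curation.** One sample per patient (first qualifying) before
  balancing, preventing patient leakage; exact 1:1 undersampling of the
  majority class; per-class 80/20 split with the rounding remainder going
  to train. Sample-level balancing is available by flag.
* **Logistic regression** by maximum likelihood (statsmodels), reference
  coding (morning bin, health-management-center division), complete-case
  with the row reduction logged; coefficients exported as odds ratios with
  95 % CIs. Perfect separation is surfaced as a warning with a BFGS
  fallback.
* **Boosted trees** (xgboost) with fixed hyperparameters — depth 8,
  learning rate 0.1, gamma 0.5, min child weight 7, 300 estimators — no
  hyperparameter search; native missing-value branches; single-thread
  `hist` for determinism.
* **AUROC** is computed exactly from mid-ranks (Mann–Whitney:
  P(s⁺ > s⁻) + ½ P(tie)); scikit-learn's implementation serves only as an
  independent cross-check in the tests.
* **Paired bootstrap** for ΔAUROC: class-stratified resampling (so every
  replicate contains both classes), percentile CI, two-sided
  p = 2·min(P(Δ≤0), P(Δ≥0)) with +1 smoothing; 2000 replicates by default.
* **Confusion metrics** at a fixed 0.5 threshold (no operating point is
  prescribed by the problem); precision is reported as missing when no
  sample is predicted positive.
* **Calibration**: ten equal-width bins on [0, 1], observed vs mean
  predicted, empty bins kept with count 0.

## IGM reporting

A sample is IGM iff it qualifies as fasting under the chosen source
(ontological, or algorithm-verified = predicted nonfasting probability
< 0.5; the theoretical label can be substituted by config), its value is
≥ 126 mg/dL, and the patient has no DM diagnosis or glucose-lowering
medication at any time up to the end of the observation window — i.e. the
measurement never led anywhere. Periods are two-calendar-year bins; counts
A–E are patient-level (a patient enters a count if any qualifying record
exists in the period), which guarantees C ≤ B ≤ A, E ≤ D ≤ A and D ≤ B.
Ratio percentages round half away from zero, one decimal for B/A, C/B and
D/A and two for E/D, matching the reporting convention of such tables.
Patients missing from the timeline table are unevaluable and counted
separately rather than assumed non-diabetic.

## Numerical choices and degenerate inputs

* Strict inequalities at every labeling threshold; thresholds computed in
  float64 by the same expression everywhere, so boundary behaviour is
  consistent between the labeler and its tests.
* `sd_reference = 0` (zero-variance stratum) reduces criterion 2 to
  g < eAG.
* Same-day duplicate resolution is stable under input shuffling (sorting
  on patient, day, timestamp, record id with a stable sort).
* The train/test split guards the floor computation against float error in
  `1 − train_fraction`.
* Bootstrap replicates with < 100 repetitions warn; single-class inputs to
  AUROC/metrics raise.

## Problem sizes

Default scales were chosen so that a full development cycle stays
interactive: pipeline and unit tests run cohorts of 600–3,000 patients;
the parameter-recovery check refits the adherence model on 50,000 patients
(~100,000 draws); the acceptance script runs a 20,000-patient pipeline and
a 4,519-sample pre-procedure validation. At these sizes the logistic
refit recovers every generator coefficient within 3 standard errors and
the holdout AUROCs stabilise to ±0.01 across seeds.

## Known limitations

* The extended (67-attribute) feature set is configuration-driven and not
  exercised by default; the 14 core covariates are hard-coded.
* The generator's division and timing mixes are patient-constant; real
  ordering behaviour varies within patients.
* `flag_igm` treats diagnosis and medication dates as a single earliest
  onset; coding lags between the two are not modeled.
* Calibration of the boosted model is reported, not corrected; no
  recalibration step is included.
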