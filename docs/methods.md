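# Methods

## Scope and unit of analysis

The package evaluates the CAM-IMC — a 0–10 point delirium screen for
non-intubated patients — against a reference-standard diagnosis, one
*observation* (a patient-day assessment by one index rater, paired with
the same-day reference rating) at a time.  Repeated observations of the
same patient are treated as independent.  This matches the primary
analysis the estimators support, but it means every confidence interval
is anti-conservative under within-patient clustering; the model layer
logs a note to that effect.  Cluster-robust or mixed-model intervals
are deliberately out of scope.

## Scoring rules and degenerate inputs

The four features are scored independently and summed: fluctuation
(0/1), RASS ≠ 0 (0/1), `min(inattention errors, 3)`, and the count of
disorientation dimensions answered in error (0–5).  The test is
positive at `total >= cutoff`; the cut-off is a parameter (default 3)
so that the per-cut-off accuracy rows at 4 and 5 are reproducible.

- **Unarousable patients** (RASS −4/−5) cannot complete the verbal
  items; such records are flagged non-assessable and excluded, the
  convention inherited from CAM-ICU practice.
- **Missing responses**: the default *strict* policy excludes the
  record (with a reasoned entry in the exclusion ledger, so that
  eligible = analyzed + excluded always holds).  A *lenient* policy
  scores the answered items — missing items contribute zero points and
  the record is marked incomplete.  Lenient scoring can only lower the
  total, so it trades sensitivity for sample retention; strict is the
  default because an imputation-or-exclusion rule is the cleaner
  contract.
- **Item dichotomisations** for the per-item analysis: inattention
  positive at ≥3 errors, disorientation positive at ≥2 dimension
  errors, the two one-point features as assessed.
- Inattention errors are total mistakes on the ten-letter task (missed
  squeezes plus false squeezes); the error types are not distinguished.
- Disorientation consumes already-adjudicated correct/error marks per
  dimension; free-text adjudication is out of scope.

## Estimators

- **Proportions** (sensitivity, specificity, PPV, NPV): exact
  Clopper–Pearson intervals in the beta-quantile formulation, with the
  boundary conventions x=0 → lower 0 and x=n → upper 1.  A zero
  denominator leaves that estimate undefined (`None`), never silently
  0/0.
- **Likelihood ratios**: log-normal (Simel) intervals,
  `se(ln LR+) = sqrt(1/tp − 1/(tp+fn) + 1/fp − 1/(fp+tn))` and the
  analogous expression for LR−.  Empty cells produce flagged
  `inf`/`nan` bounds (`degenerate=True`).
- **AUROC**: computed twice on every call — trapezoidal integration of
  the threshold-sweep ROC curve and the Mann–Whitney midrank
  statistic — and asserted equal to 1e−10; ties are therefore handled
  identically in both routes (diagonal segments / half-credit).  The
  variance is DeLong's `S10/m + S01/n` from the placement-value sample
  variances, computed with sorted searches rather than the m×n outer
  product; the normal-approximation CI is truncated to [0, 1].
- **Per-cut-off AUROC** is the AUROC of the *dichotomised* test at that
  cut-off (equal to (sens+spec)/2); the single overall AUROC is
  computed on the raw 0–10 score.  Only this pairing makes the two
  kinds of AUROC simultaneously meaningful in one report.
- **Youden selection** maximises J = sens + spec − 1; ties break toward
  the lowest cut-off, favouring sensitivity, which is the right
  direction for a screening instrument.
- **Cohen's κ** uses the Fleiss–Cohen–Everitt large-sample SE with a
  normal CI (cross-checked against statsmodels in the test suite).
  Both-raters-constant-and-equal (chance agreement 1) is flagged
  undefined.  κ is computed on test positivity at the primary cut-off
  over patient-days assessed by both index raters.
- The internal normal quantile is kept at full precision
  (1.959963984…); rounding — half-up to two decimals — happens only at
  display and report export.

## The synthetic cohort

The generator exists so the whole pipeline is testable end-to-end
without patient data.  Its defaults emulate a prospective
cardiac-surgery IMC cohort: 155 patients (age ≥50, median 68,
IQR 61–73, 21.3% female, Mini-Cog median 4 with IQR 2–5), 3
postoperative days, two index raters and one reference rater,
observation-level delirium prevalence 54/624 ≈ 8.7%, uniform
index-assessment missingness 1 − 624/930 ≈ 0.33, and index-rater
agreement κ = 0.80.

Generative model and calibration:

- **Latent states**: a two-state Markov chain per patient.  Day-1
  prevalence equals the target observation prevalence; the onset
  probability is solved so the marginal stays constant across days
  (persistence default 0.5 — the duration of delirium episodes is a
  free choice, as only prevalence is identified by the emulated
  figures).  A helper converts a patient-level ("ever delirious")
  incidence target into the equivalent day-1 prevalence.
- **Feature responses** conditional on state: fluctuation and RASS ≠ 0
  are Bernoulli at the configured sensitivities/false-positive rates
  (defaults: 0.83/0.19, 0.35/0.11); inattention error counts (0–10)
  follow a geometric-family pmf `w_k ∝ r^k` whose ratio is solved by
  root-finding so that P(errors ≥ 3 | state) matches the configured
  rate (0.83 / 0.01) — a proper decaying geometric cannot exceed
  P ≈ 0.73 and so cannot represent the delirious state; disorientation
  dimension errors are Binomial(5, q) with q solved so that
  P(errors ≥ 2 | state) matches (0.80 / 0.01), the errors assigned to
  uniformly random dimensions.  Because only the dichotomised rates
  are identified, the count *shapes* are modelling choices.
- **Between-rater correlation**: each feature of each patient-day has a
  shared standard-normal severity latent; each rater sees
  `z = sqrt(λ)·z_shared + sqrt(1−λ)·ε` mapped through the probability
  integral transform onto that feature's conditional distribution.
  Sharing per *feature* (not one scalar per patient-day) keeps features
  conditionally independent within a rater, so the marginal operating
  characteristics of the total score have a closed convolution form
  (`expected_score_distribution`) that parameter-recovery tests compare
  against.  λ is calibrated to the target κ by Brent root-finding on a
  20 000-patient-day fixed-seed simulation with common random numbers;
  an infeasible target (below the state-sharing-only κ, ≈0.55 at the
  defaults) raises an error naming the feasible range.
- **Reference rater** reports the latent state, flipped with a
  configurable error probability (default 0, i.e. reference = truth).
- **Covariates**: age is skew-normal, fitted to the median/IQR by least
  squares on the three quartiles (the three-parameter family cannot
  always interpolate three quartiles exactly; residuals up to a
  quarter-year are accepted) and truncated to [50, 95]; sex is
  Bernoulli; Mini-Cog and baseline orientation are categorical
  distributions chosen to reproduce the target median and IQR.
- **Determinism**: one `numpy` Generator seeded from the config (or an
  override) drives everything; identical config + seed give
  byte-identical CSVs.

What the generator does *not* emulate: within-patient correlation of
responses beyond the latent state and the day-to-day Markov chain;
informative (e.g. staffing-driven) missingness; delirium motor
subtypes; any association between covariates and delirium risk (age
and Mini-Cog are drawn independently of the latent state, so subgroup
analyses on simulated data have the same expected accuracy as the
whole cohort).  Passing recovery tests therefore show the estimators
and plumbing are correct under the stated model — not that the
instrument would achieve these characteristics in another clinical
population.

The generator's implied total-score accuracy at cut-off 3
(sens ≈ 0.99, spec ≈ 0.96 by the convolution) is somewhat better than
the published instrument-level figures; this is a consequence of
composing the published *item* characteristics under conditional
independence, and the recovery tests compare simulated output against
this analytic truth, not against the instrument-level figures.

## Problem sizes and tolerances

Parameter-recovery checks run on a 10 000-patient cohort (~40 000
index observations, ~13 500 rater pairs) with 3 Monte-Carlo-SE bands;
interrater κ is required within ±0.05 of target; Clopper–Pearson
coverage uses 2000 replicates at (n=54, p=0.9) with a 3-SE allowance
below the nominal level (the exact interval is conservative, so
observed coverage sits above 95%); the trapezoid/Mann–Whitney duality
is asserted to 1e−10 on every call and fuzzed over hundreds of small
integer-score instances.  The whole suite runs in well under a minute
on one CPU.

## Known discrepancies and limitations

- The published NPV interval for the cut-off-3 row (printed as
  0.90–1.00) is not the Clopper–Pearson interval of 538/540
  (≈0.987–1.000); the package reports the computed interval.
- The published upper sensitivity bound 1.00 for 52/54 corresponds to
  the computed 0.9955 after half-up rounding.
- Likelihood-ratio intervals use the log method, which reproduces the
  published bounds, even though proportions use Clopper–Pearson.
- No DeLong *comparison* test between correlated AUROCs, no bootstrap
  CIs, no multi-category κ, no plotting beyond ROC-coordinate export.
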