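# Methods

## Phenotype model

A participant-wave is scored on five binary components; the score is their
sum and the state is robust (0), pre-frail (1–2) or frail (≥3).

**Absolute components.** Weight loss is flagged when
(weight_at25 − weight_current)/weight_at25 ≥ 0.15, with the boundary
included ("at least 15%"). Exhaustion is flagged for a "no" answer to the
single energy item of the Geriatric Depression Scale.

**Quintile components.** Low activity, weakness and slowness are flagged
relative to cohort-derived cut-offs:

- *low activity*: PASE score at or below the cohort-wide empirical 20th
  percentile (unstratified — no stratifier is defined for this component);
- *weakness*: best-side grip (the larger of the two per-side trial means,
  "mean-then-max") at or below the 20th percentile of its gender ×
  within-gender-BMI-quartile cell;
- *slowness*: best (fastest) 4-m walk time at or above the 80th percentile of
  its gender × height-stratum cell, the strata split at the gender median
  height.

All quantiles use the empirical distribution with linear interpolation
between order statistics. The flag rule is **inclusive at the cut-off**
(≤ for low-is-bad values, ≥ for walk time): "lowest quintile" includes its
boundary, and inclusiveness makes the degenerate all-tied cell well defined
(everyone flagged). Cells smaller than 20 observations are pooled
deterministically — a small grip cell merges with its smaller adjacent BMI
quartile (lower index on ties); an undersized walk stratum collapses to a
gender-wide cut-off. BMI values outside the derivable range fall in the
nearest boundary quartile.

Thresholds are derived from baseline observed (pre-imputation, unweighted)
records and frozen; follow-up waves are classified against them, so state
changes reflect the person, not drifting cut-offs. Eligibility (age ≥ 60,
MMSE ≥ 9) is enforced at load, before threshold derivation.

## Transition taxonomy

Between the two waves a state pair is *improved* when follow-up is strictly
less frail, *worsened* when strictly more frail, *unchanged* otherwise.
Two-level moves (frail↔robust) are annotated but are not a fourth category.
Participants missing either state are excluded and reported as attrition.
The transition matrix carries raw counts, weighted row-conditional
proportions with design-based CIs, and category proportions both weighted
and unweighted — the two can legitimately differ under a complex design, so
both are always reported.

## Survey estimation

The design is two-stage cluster sampling with simple random selection of
enumeration blocks (EBs) and then living quarters (LQs). Weights are
inverse inclusion probabilities, w = (EB_total/EB_selected) ×
(LQ_total/LQ_selected), with per-EB LQ frame sizes configurable. Proportion
variance uses first-stage between-EB Taylor linearisation under the
with-replacement approximation (no second-stage finite-population
correction); CIs are built on the logit scale and back-transformed, with a
one-sided exact-style (Clopper–Pearson) bound for degenerate 0/1
proportions. Association tests run on unweighted counts: Pearson chi-square,
switching to Fisher's exact (2×2) or a fixed-seed Monte-Carlo exact test
with fixed margins (larger tables) when any expected count is below 5. A
first-order design-effect correction of the chi-square is available behind a
flag but is not the default.

## Predictor models

Risk sets are the structurally possible ones: participants not frail at
baseline can worsen; participants not robust at baseline can improve (a
config switch uses all followed participants instead, and results under both
denominators can be produced). Models are binary logistic fits with Wald
CIs; screening retains a candidate when any non-reference level has p < 0.25
univariately; the multivariable model always includes age group and gender
and removes the worst remaining variable (largest variable-level p ≥ 0.05)
one at a time. Aliased (collinear) columns are dropped deterministically,
later-listed first, and recorded on the result. Separation is flagged, not
raised.

## Imputation

Chained equations over component flags (logistic conditional draws) and
high-missingness covariates (predictive-mean matching: draw a random donor
among the `donor_count` nearest predicted values). Covariates qualify above
5% missingness; component inputs qualify at any missingness. Each of the m
chains starts from a random fill from observed values and sweeps the targets
`iterations` times. Defaults m = 20, iterations = 10, donor_count = 5 —
deliberate package choices, not reconstructions of any published setting.
Frailty state and transition category are always re-derived inside each
completed dataset (passive imputation). Pooling follows Rubin's rules with
Barnard–Rubin degrees of freedom (normal quantiles when the
between-imputation variance is zero). When the pooled analysis is an
exposure–outcome model, the outcome must be included among the imputation
predictors, or the association attenuates toward the null.

## Synthetic cohort generator

**What it emulates.** A rural cohort aged 60+, 2,324 baseline participants
spread over 156 of 254 enumeration blocks with 16 LQs sampled per block
(LQ frame size defaults to 100 per block, a fixed value inside the reported
80–120 range); baseline states (32.7%, 57.9%, 9.4%); a 12-month transition
matrix with rows (47.5, 49.6, 2.9), (28.1, 62.9, 8.9), (6.1, 44.9, 48.9)% —
rows renormalised from one-decimal percentages; 20.2% attrition (exactly
round(n·rate) records dropped uniformly; a switch makes attrition rise with
baseline severity for sensitivity studies, since nothing is known about who
drops out). Demographic margins (age bands, gender, ethnicity, education,
income, chronic-disease counts) follow the emulated cohort's baseline
distribution. Component propensities are proportional to the component
prevalences (8.6, 31.7, 24.2, 22.7, 20.8)%.

**State mode and the reference thresholds.** In state mode each participant
carries a latent state; a component vector consistent with it is drawn
(0 flags for robust, uniform 1–2 for pre-frail, uniform 3–5 for frail;
which components via weighted sampling without replacement), and raw
measurements are synthesised on the correct side of a *fixed reference
ThresholdSet* with margins that absorb output rounding. Classifying a
state-mode cohort against these frozen reference thresholds recovers the
latent state of every record exactly — including degenerate configurations
such as an all-robust cohort. Re-deriving quintile thresholds from the
generated cohort itself cannot reproduce such configurations (a quintile
rule always flags about 20% of any cell), which is precisely why state-mode
cohorts ship with their reference thresholds; cohort-relative derivation is
exercised in raw mode and by the brute-force quantile oracle suite. The
reference values (PASE cut-off 60; grip cut-offs 24–30 kgf for men and
14–18 kgf for women rising over BMI quartiles; median heights 163/151 cm;
walk cut-offs 5.5–6.5 s) are plausible constants for a rural South-East
Asian cohort aged 60+ and are configurable.

**Exposures.** A configured binary exposure tilts the transition draw: the
configured log-odds-ratio is applied to the row's probability mass on the
target category (worsened or improved) and the row renormalised, so a
logistic regression of the category on the exposure *conditional on baseline
state* recovers the configured OR in expectation. Marginal (collapsed) ORs
are attenuated by differing base rates across rows — non-collapsibility —
so marginal-OR recovery experiments assign the outcome directly from a
logistic model whose intercept is solved to hit the configured marginal
proportion (`simulate_binary_exposure_outcome`).

**Missingness.** Missing-at-random masking: per field, the missingness
probability is a logistic function (slope 0.5 per standardised driver,
default driver age) with the intercept calibrated by root-finding so the
marginal rate matches the configured one. Drivers are never masked. Default
missing rates are zero; nonzero rates are an explicit configuration choice.

**What it does not emulate.** Death and competing risks (the transition
space is the three living states); item-level instrument responses (PASE,
GDS, DSSI, MMSE enter as scores); measurement error correlated across
components; informative attrition (off by default); seasonal or assessor
effects. Consequently, passing round trips demonstrate the correctness and
calibration of the *pipeline* — classifier, tabulation, weighting,
regression, imputation — not the realism of any particular measurement
distribution.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.Generator` seeded from the
config; identical config + seed gives byte-identical output files. Derived
sub-streams use `SeedSequence` spawning so baseline, follow-up and
missingness draws are independent. Experiment sizes in the validation suite
mirror the emulated study (n = 2,324 with 100 replicates for baseline
recovery; n = 605/1,855 with 200 replicates for transition and OR recovery;
500 random cohorts of 50–5,000 for the quantile oracle; 1,000 replicates for
CI coverage) — sizes chosen so Monte-Carlo error is well inside each check's
tolerance while a full run stays fast on a single CPU. Ties at quantile
cut-offs are flagged by the inclusive rule; degenerate proportions use exact
bounds; logistic fits cap at 200 Newton iterations with |β| > 15 treated as
separation.

## Known limitations

- The weight formula and variance treatment reconstruct a standard two-stage
  design; the emulated study does not publish its exact weighting, so other
  defensible reconstructions exist.
- The MMSE band table (normal 24–30, mild 18–23, moderate 10–17, moderately
  severe 9) is a configurable default, not an asserted guideline.
- Whether quintile thresholds should be derived before or after imputation,
  weighted or unweighted, per wave or frozen at baseline is undocumented in
  the literature this pipeline follows; the package freezes baseline
  observed unweighted thresholds and exposes the alternatives as options.
- Row-tilted exposures produce conditional, not marginal, odds ratios; users
  comparing against marginal estimates should use the direct-assignment
  simulator.
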