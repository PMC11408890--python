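# Methods

This note documents the models, rules, and numerical choices implemented in
`actiqol`, the design decisions made where the underlying conventions are
genuinely open, and what the synthetic-data validation does and does not
establish.

## Epoch processing

Accelerometer data enter as minute epochs (counts per minute, CPM),
0-based and day-partitioned into 1440-minute days, at most 7 days per
participant. All interval rules operate within a day; bouts and non-wear
windows do not cross midnight (a crossing-midnight event would have to
straddle the device's day boundary, a negligible and conventionally ignored
case).

**Intensity cutpoints.** Sedentary CPM < 100; moderate 2000 ≤ CPM ≤ 5998;
vigorous CPM ≥ 5999. The 100–1999 band is labeled *light*: it counts toward
wear time but contributes no MVPA. The cutpoints are configurable
(`IntensityThresholds`) with these values as defaults.

**Non-wear.** A maximal window of zero-count minutes spanning ≥ 60 minutes
is device-off time; interior runs of sub-100 CPM minutes shorter than
2 minutes (i.e. at most one whole minute, since epochs are whole minutes)
are tolerated, absorbed into the window, and counted as non-wear. Any
CPM ≥ 100 minute, or a sub-100 run of ≥ 2 minutes, terminates the window;
tolerated runs do not reset the 60-minute counter. The span threshold is
implemented as ≥ 60 (the standard convention for "longer than 60 minutes"
rules on minute epochs); a `strict_gt` flag switches to > 60. Windows begin
and end with zero-count minutes — a tolerated sub-100 run at the edge of a
window belongs to wear.

**Wear validity.** A day is valid with ≥ 600 wear minutes (recorded minutes
minus non-wear); a participant is valid with ≥ 4 valid days. Both bounds
are configurable (`ValidityRule`).

**Bouts.** A bout is a maximal run of MVPA-labeled minutes, merged across
interior sub-MVPA runs of at most one minute, with total span ≥ 10 minutes.
Interruption minutes count toward the span but contribute zero MET-minutes:
the tolerance makes an interrupted effort *qualify*, but crediting
sub-threshold minutes with MVPA energy expenditure would inflate the
exposure. Greedy merging across tolerated interruptions yields the unique
maximal partition, so detection is deterministic.

**Weekly MET-minutes.** Daily MET-minutes are 4 × moderate + 8 × vigorous
minutes (one vigorous minute counts as two moderate minutes), summed over
all MVPA wear minutes (MVPA-AT) or over qualifying-bout minutes only
(MVPA-AB). The weekly value averages daily MET-minutes over *valid days
only* and scales to 7 days (`mean7`). This normalization is a design
choice: with 4–6 valid days a raw sum would penalize shorter valid weeks
relative to the fixed 600 MET-minutes/week guideline, so the default
extrapolates the valid-day mean; a `sum` option provides the raw
alternative. Zero valid days make the exposure undefined and raise an
error — validity filtering is expected upstream.

## EQ-5D-3L scoring

The Korean tariff is the default value set: constant 0.050, N3 0.050, and
level-2/level-3 decrements M (0.096, 0.418), SC (0.046, 0.136),
UA (0.051, 0.208), PD (0.037, 0.151), AD (0.043, 0.158). Two conventions
required decisions:

* The constant is applied only when at least one dimension exceeds level 1,
  so perfect health (11111) scores exactly 1.0 — the standard valuation
  convention; applying it unconditionally would score perfect health 0.95.
  A `literal_formula` switch evaluates the additive formula unconditionally
  for comparison.
* N3 is the indicator that any dimension is at level 3, applied once.

Under these defaults the 243 states span [−0.171, 1.0], and the index is
weakly decreasing in every dimension (verified exhaustively in tests).

**Dichotomization.** HRQoL is split at the cohort mean index: below the
mean is low QoL. An index exactly equal to the mean goes to the high group
(the low group is defined as *below* average); the tie rule is
configurable. The mean is learned from the analytic sample (after
exclusions), which is where the published analysis dichotomizes.

## GPAQ scoring

Weekly self-reported minutes in three domains (occupation, commuting,
leisure) are combined with the same MET weights and threshold:
4 × (moderate + commuting) + 8 × vigorous ≥ 600. Commuting is weighted as
moderate activity, the standard GPAQ analysis convention. Session-level
screening ("at least 10 minutes per episode") is assumed already applied by
the questionnaire instrument; the module only enforces non-negativity and a
7 × 1440 minutes/week plausibility cap.

## Inference

* **Crude OR.** For the 2×2 exposure (≥ 600 vs < 600 MET-min/week) ×
  outcome (low/high QoL) table, OR = ad/bc oriented so that OR > 1 means
  compliant participants have higher odds of *high* QoL, with the Woolf CI
  exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)). This orientation reproduces
  the published estimates, whose headline treats high HRQoL as the outcome
  success; the inverse ("risk of low HRQoL") is its reciprocal. Zero cells
  receive the Haldane–Anscombe 0.5 correction and are flagged.
* **Chi-square.** Pearson Σ(O−E)²/E without continuity correction,
  df = (r−1)(c−1); zero marginals are an error.
* **t test.** Pooled-variance two-sample t by default (the published
  analysis does not state the variant) with a Welch option.
* **Logistic regression.** Self-contained maximum-likelihood fit by
  Fisher scoring / IRLS from a zero start; convergence when the maximum
  absolute score < 1e-8, capped at 25 iterations. The covariance is the
  inverse observed information at the optimum; CIs are Wald on the log-odds
  scale, exponentiated for reporting. Rank deficiency is detected before
  fitting by pivoted QR on the column-scaled design and reported by column
  name; separation is flagged when coefficients diverge (|β| > 30 during
  iteration, or non-convergence with |β| > 10) and reported with the
  offending term. Model 1 adjusts for age (continuous), sex, marital
  status, education, employment, and income; Model 2 adds stress,
  subjective health, and depression. Categorical covariates are
  dummy-coded against first-listed reference categories (male, single,
  lowest education, white collar, low income, little stress, poor health,
  no depression). No survey weights are used.

## Exclusion cascade

Enrollment exclusions are applied in a fixed order — device lost,
non-wearer, mechanical error, insufficient wear, missing EQ-5D, pregnancy,
cancer treatment, arthritis — with first-match attribution: a participant
matching several criteria is counted once, at the earliest step. The report
conserves counts at every step. Missing covariate values in model columns
fail fast with a per-column report rather than being imputed.

## Synthetic cohort generator

The generator emulates the *structure* the analysis assumes, with defaults
set to the study conditions: n = 1298 analyzable adults over 7 days;
~14 h/day wear windows (SD 1.5 h) flanked by zero-count off-body time, plus
Poisson(0.3/day) device-off gaps of 60–120 minutes; a latent active class
(prevalence 0.2257, the bout-compliance prevalence of the study sample)
receiving qualifying 10–40-minute bouts until a weekly target of 700–2000
MET-minutes is reached, while everyone receives fragmented 1–9-minute MVPA
spells (3.65/day, calibrated so total-MVPA compliance lands near the
study's ~0.59); high QoL drawn with logit = α + log(1.55)·meets-AB +
covariate effects, with α solved by root-finding so the high-QoL prevalence
equals 1005/1298; covariate marginals taken from the high-QoL column of the
descriptive table, with effect directions and magnitudes mirroring its
group contrasts; GPAQ self-report as the participant's true total-MVPA
MET-minutes plus a floor, scaled by a log-normal multiplier whose *mean*
exceeds 1 (over-reporting on average) but with enough dispersion
(σ = 0.8) that the self-reported exposure is only weakly associated with
the outcome, as observed for questionnaire measures.

Reproducibility: one seed sequence per cohort, with per-participant child
seeds, so identical seeds give byte-identical output and any participant
can be regenerated independently.

**Exactness by construction.** Compliance flags that drive the outcome are
computed from the planned bout arithmetic, and the epoch painter guarantees
the actigraphy module recovers that plan exactly: planned gaps are flanked
by two forced light minutes so zero-runs cannot leak across wear
boundaries, MVPA events keep ≥ 2 sub-MVPA minutes of separation so they
never merge, wear windows keep ≥ 60-minute margins to the day edges so
off-body time is always detected, and the within-wear zero-count rate
(0.57 × 0.30 per minute) makes a spurious 60-minute zero window
astronomically unlikely. Tests assert exact agreement between ground truth
and the processed streams.

**EQ-5D response model.** High-QoL participants are perfect (80%) or carry
a single mild level-2 complaint; low-QoL participants carry one or two
level-3 dimensions plus optional level-2 complaints. This separates the two
latent classes across the cohort-mean split by a wide margin, so the
mean-split label reproduces the latent outcome essentially without
misclassification. That is deliberate: it makes the generating exposure
odds ratio identifiable end-to-end, which is what the parameter-recovery
validation needs.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: complex-survey sampling design and weights;
circadian and seasonal activity patterns beyond a single daily wear window;
EQ-5D response heterogeneity that overlaps the mean split (real cohorts
misclassify near the threshold, attenuating associations); correlated
missingness; and device-level measurement error within intensity bands
(CPM values are drawn from discretized log-normals within each band — only
band membership matters downstream).

## Validation and problem sizes

* Bout and non-wear detection are checked against brute-force scanning
  oracles implementing the verbatim rules, over thousands of seeded random
  streams in the test suite plus property-based (hypothesis) cases.
* The crude OR column, compliance percentages, chi-square p, exclusion
  cascade, and tariff table are checked exactly against their published
  values. One published figure does not verify: the total-MVPA crude OR
  prints as 1.15 while the cross-product of the published counts is 1.157
  (→ 1.16 at two decimals); the CI (0.89–1.51) verifies exactly, so the
  point estimate is checked to within one unit in the last printed digit.
* Parameter recovery runs the complete pipeline (simulation → epoch
  processing → scoring → exclusion → adjusted logistic fit) on 40
  replicate cohorts of n = 1298 and checks Wald 95% CI coverage of the
  generating OR (1.55) at ≥ 90%; the replicate count balances Monte-Carlo
  resolution against the cost of processing ~13 million minute epochs per
  replicate.

## Known limitations

* Adjusted-model coefficients from the original individual-level data are
  not reproducible (the data are not packaged); the adjusted machinery is
  validated structurally by parameter recovery and by the
  confounding-attenuation direction test instead.
* The Woolf CI uses 1.96 rather than profile likelihood; for the cell
  counts involved the difference is far below reporting precision.
* GPAQ cleaning beyond the plausibility cap (outlier truncation rules) is
  out of scope.
* The separation heuristic (coefficient divergence) is a practical
  detector, not a certificate; linear-programming separation tests would be
  definitive but are unnecessary at these sample sizes.
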