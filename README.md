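# actiqol

Accelerometer-measured physical activity and health-related quality of life
(HRQoL) in adults: a reusable, tested implementation of the full analysis
pipeline used in population studies that pair hip-worn ActiGraph minute-epoch
counts with the EQ-5D-3L instrument — epoch processing, instrument scoring,
and epidemiological inference — together with a synthetic cohort generator so
every stage can be exercised and validated without access to restricted
survey data.

It is written for epidemiologists and methods researchers who need the
minute-epoch conventions of the actigraphy literature (Troiano-style
counts-per-minute cutpoints, the 60-minute zero-run non-wear rule, 10-minute
bout detection with interruption tolerance, wear-validity filtering, weekly
MET-minutes) as composable, scikit-learn-style components.

## The analysis

**Exposures.** Minute epochs are classified by counts per minute (CPM):
sedentary < 100, light 100–1999, moderate 2000–5998, vigorous ≥ 5999.
Non-wear time is any run of ≥ 60 minutes of zero counts, tolerating interior
sub-100 CPM runs shorter than 2 minutes. A day is valid with ≥ 10 hours of
wear; a participant is valid with ≥ 4 valid days. Weekly moderate-to-vigorous
physical activity (MVPA) is expressed in MET-minutes/week,

    MET-min/week = 4 x moderate minutes + 8 x vigorous minutes,

under three definitions: **MVPA-AT** (every MVPA minute), **MVPA-AB** (only
minutes inside sustained bouts of span ≥ 10 minutes, tolerating sub-threshold
interruptions < 2 minutes), and **MVPA-S** (GPAQ self-report, occupation +
commuting + leisure). Guideline compliance is ≥ 600 MET-minutes/week.

**Outcome.** EQ-5D-3L responses are scored with the Korean tariff,

    index = 1 − (0.050·I[any level>1] + Σ level decrements + 0.050·I[any level 3]),

and dichotomized at the cohort mean into low/high HRQoL.

**Inference.** Compliance–HRQoL association is estimated as the odds ratio
of high HRQoL for compliant vs non-compliant participants: crude (2×2
cross-product with Woolf 95% CI), adjusted for socioeconomic covariates
(Model 1), and further for mental-health covariates (Model 2), via a
maximum-likelihood logistic regression fitted by iteratively reweighted
least squares with Wald intervals.

## Worked example

```python
from actiqol import CohortConfig, simulate_cohort, run_study

cohort = simulate_cohort(CohortConfig(n_participants=1298, seed=1))
result = run_study(cohort.participants, cohort.streams)

print(f"analytic n = {len(result.analytic)}")
print(f"mean EQ-5D index = {result.mean_index:.4f}")
row = result.table3.set_index("exposure").loc["MVPA-AB (10 min bouts)"]
print(f"crude OR  = {row.crude_or:.2f} ({row.crude_ci_low:.2f}-{row.crude_ci_high:.2f})")
print(f"model 2 OR = {row.model2_or:.2f} ({row.model2_ci_low:.2f}-{row.model2_ci_high:.2f})")
```

prints

```
analytic n = 1298
mean EQ-5D index = 0.8749
crude OR  = 1.42 (1.02-1.97)
model 2 OR = 1.44 (1.02-2.04)
```

i.e. on this synthetic cohort (generated with a true conditional exposure OR
of 1.55 for bout-qualified compliance) participants meeting the guideline in
sustained ≥ 10-minute bouts have about 1.4–1.5 times the odds of high HRQoL,
and the covariate-adjusted estimate brackets the generating value.

The same pipeline is available from the shell:

```bash
actiqol simulate --n 1298 --seed 1 --out cohort/
actiqol analyze --participants cohort/participants.csv \
                --epochs cohort/epochs.csv.gz --out analysis/
```

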