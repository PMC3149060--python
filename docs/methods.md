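# Methods

## Surveillance problem

External CSF drainage (ventricular, EVD; lumbar, ELD) carries a substantial
risk of bacterial meningitis/ventriculitis (DRM). The surveillance unit is
the **drainage episode**: from first drain placement to the last removal plus
a 7-day incubation window, capped at hospital discharge. Readmissions within
30 days of discharge are folded into the preceding episode. Episodes are
excluded when the patient died within one day of placement, was younger than
18, had a pre-existing CNS infection, carried two drains simultaneously, had
the drain placed in another centre, was admitted for less than one day, was
readmitted after more than 30 days, or had a non-cranial/non-lumbar external
drain site. When both drain types occur in one episode the episode is
classified EVD.

## Feature extraction

Each candidate predictor is summarised by its **worst value** over the
episode: the maximum for inflammatory and cell-count markers (CRP, blood and
CSF leukocytes, CSF protein, …) and the minimum for hemoglobin and CSF
glucose. Derived terms:

* CRP enters the model as a third-degree polynomial: `crp`, `(crp/10)^2`,
  `(crp/100)^3`.
* CSF leukocytes enter as `ln(count + 1)`.
* **Contaminant correction**: a coagulase-negative staphylococcus isolate
  counts as a true positive only if systemic antibiotic therapy started
  between one day before and three days after the sampling day; otherwise it
  is treated as contamination. Other organisms always count.
* **Empiric therapy**: vancomycin + ceftazidime both started on day 4 or
  later, or ceftriaxone + flucloxacillin both started by day 4, with start
  days at most one day apart.
* `n_abx_started` counts distinct systemic antibiotic agents started during
  the episode.

Episodes without any CSF culture have `culture_positive` missing rather than
negative.

## Missing data

Multiple imputation by chained equations (`statsmodels` `MICEData`,
predictive mean matching) with m completed datasets; each chain is seeded
independently, so runs are fully reproducible. Estimates are pooled with
Rubin's rules: total variance `T = W̄ + (1 + 1/m)B` with the Rubin
small-sample degrees of freedom. Predictive mean matching draws only
observed values, which keeps binary variables binary without a separate
model. A single "mean dataset" (cell-wise mean, majority vote for binaries)
is used for apparent-performance evaluation.

## Model development

1. **Univariate screening** at α = 0.05: chi-square for binaries, t-test for
   approximately normal, Mann–Whitney for skewed variables.
2. **Multivariable logistic regression** (maximum likelihood). If separation
   or exploding standard errors are detected the fit falls back to Firth's
   Jeffreys-penalised likelihood.
3. **Backward selection** on Rubin-pooled Wald p-values, dropping the least
   significant predictor at each step. The linear CRP term is protected
   while any higher-order CRP term remains in the model (polynomial
   hierarchy).
4. **Internal validation** by Harrell's bootstrap: models refitted in
   bootstrap resamples are evaluated on the original data; the mean
   calibration slope gives the shrinkage factor, the mean AUC drop gives the
   optimism. Coefficients are multiplied by the shrinkage factor and the
   intercept refitted by a logistic fit with the shrunk linear predictor as
   offset, so the rule remains calibrated in the large. The corrected AUC is
   the final rule's apparent AUC minus the bootstrap optimism.
5. The resulting rule (intercept, coefficients, shrinkage, provenance) is
   serialised to JSON. Rules may also be assembled from published odds
   ratios; the intercept is then calibrated to a target prevalence on a
   reference population by root-finding.

## Evaluation and surveillance

* Sensitivity/specificity/PPV/NPV with **exact Clopper–Pearson** intervals
  (beta-quantile form). Displayed intervals never print an unattained 0% or
  100%: a bound that rounds to the boundary without reaching it is shown one
  display unit inside (e.g. 81/82 → upper bound displayed 99.9).
* AUC by the rank statistic with ties counted one half; variance and CI by
  DeLong's placement-value method.
* Classification is strict: an episode is flagged only when P > cutoff. The
  standard cutoffs are 0.107 (high-sensitivity) and 0.175.
* Per-period surveillance: expected infections = Σ of predicted
  probabilities, with a normal interval using `var = Σ p(1−p)`; observed
  counts get exact Poisson intervals; rates are per 1000 drain-days.

## Synthetic cohort generator

No patient-level data are distributed. The generator emits event-level
tables (patients, drains, labs, cultures, antibiotics, outcomes) calibrated
to published *group* statistics:

* A latent DRM flag ~ Bernoulli(0.153) drives all group-specific
  distributions; predictors are **conditionally independent given the
  flag** — a deliberate simplification (real predictors are mutually
  correlated; see limitations).
* Worst values are drawn from lognormal (skewed analytes) or clipped normal
  (percentages) distributions parameterised from (median, q1, q3):
  `mu = ln(median)`, `sigma = (ln q3 − ln q1)/(2 · 0.6745)`. This preserves
  the median and the quartile *ratio* exactly; the absolute quartiles shift
  when the median is not the geometric midpoint of the quartiles.
* The episode extremum is drawn first; the remaining measurements are
  scattered strictly on the non-extreme side, so the observed worst value
  equals the calibrated draw.
* Antibiotic counts are negative binomial with parameters solved by grid
  search from (median, q1, q3) targets; empiric-therapy pairs are injected
  consistently with the detection rule; CoNS-positive cultures are anchored
  to antibiotic starts (or relabelled) so the *corrected* positivity matches
  the target, and contaminants appear only in untreated windows.
* Missingness is whole-episode per variable, with optional
  missing-at-random dependence on the outcome solved by root-finding so the
  marginal rates match footnoted targets.
* The generator emits an already-eligible cohort (age ≥ 18, no pre-existing
  CNS infection, deaths never within a day of placement): `n_patients`
  targets the post-exclusion cohort size. Exclusion handling is exercised by
  constructed fixtures in the tests.

### Known simplifications

* Conditional independence given the outcome flag inflates the apparent
  discrimination of models fitted to synthetic cohorts (AUC ≈ 0.98 vs
  ≈ 0.93 expected with realistically correlated predictors).
* Lab values have no within-episode autocorrelation or trend.
* Culture organisms other than CoNS are drawn from a fixed frequency list.

Problem sizes used in the test-suite simulations (cohort sizes, replication
counts, bootstrap B) are the package's own choices, selected for statistical
power within the runtime budget before outcomes were inspected.
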