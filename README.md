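# drainsurv

Automated surveillance of external drain-related meningitis and ventriculitis
(DRM) in neurosurgical patients.

Patients with an external ventricular drain (EVD) or external lumbar drain
(ELD) are at high risk of bacterial meningitis/ventriculitis. Conventional
surveillance means reviewing every chart by hand. `drainsurv` implements an
alternative: a multivariable prediction model, built from routinely collected
clinical data, that assigns each drainage episode a probability of DRM.
Episodes below a probability cutoff are classified negative without review;
only the high-probability minority needs manual confirmation. At the lower of
the two standard cutoffs this keeps sensitivity near 99% while eliminating
roughly three quarters of the chart review workload.

The package provides the complete pipeline:

| module | purpose |
|---|---|
| `drainsurv.synth_cohort` | synthetic event-level cohort generator calibrated to published group statistics |
| `drainsurv.episodes` | episode construction (placement → removal + 7 days, capped at discharge), readmission folding, eligibility exclusions |
| `drainsurv.features` | worst-value feature extraction, contaminant correction, empiric-therapy detection, CRP polynomial terms |
| `drainsurv.imputation` | multiple imputation by chained equations with Rubin pooling |
| `drainsurv.model` | univariate screening, (Firth-fallback) logistic regression, backward selection with polynomial-hierarchy protection, bootstrap optimism correction and shrinkage |
| `drainsurv.evaluation` | exact binomial (Clopper–Pearson) intervals, DeLong AUC, calibration, per-period surveillance summaries |
| `drainsurv.pipeline` / `drainsurv.cli` | end-to-end orchestration with a deterministic manifest |

## Worked example

Run the full pipeline — simulate a 537-patient cohort, build episodes,
extract features, impute, develop and internally validate the model, and
produce surveillance summaries:

```console
$ drainsurv run-all --n 537 --seed 1 --m 5 --bootstrap 50 --out demo
{
  "n_episodes": 537,
  "selected_predictors": [
    "drain_type_evd",
    "n_drains",
    "blood_leukocytes",
    "csf_leukocytes_log",
    "culture_positive",
    "empiric_abx",
    "n_abx_started"
  ],
  "auc_apparent": 0.9838041014869272,
  "auc_corrected": 0.9799085864373194
}
```

`demo/` then contains the raw event tables, the episode and feature tables,
`model.json` (the portable prediction rule) and `report.json` (screening
results, selection trace, bootstrap validation, confusion matrices at both
cutoffs, calibration table and yearly surveillance summaries).

The evaluation utilities also work directly on counts. Classifying 537
episodes at the low cutoff with 81 true positives, 55 false positives,
1 false negative and 400 true negatives:

```pycon
>>> from drainsurv.evaluation import confusion_from_counts
>>> confusion_from_counts(81, 55, 1, 400).as_dict()
{'cutoff': nan, 'tp': 81, 'fp': 55, 'fn': 1, 'tn': 400, 'n': 537,
 'flagged_fraction': 25.3,
 'sensitivity': 98.8, 'sensitivity_ci': (93.4, 99.9),
 'specificity': 87.9, 'specificity_ci': (84.6, 90.8),
 'ppv': 59.6, 'ppv_ci': (50.8, 67.9),
 'npv': 99.8, 'npv_ci': (98.6, 99.9)}
```

i.e. at ~99% sensitivity only 25.3% of charts still need manual review.
Intervals are exact Clopper–Pearson; displayed bounds never print an
unattained 0% or 100% (a bound that rounds to the boundary but does not reach
it is shown one display unit inside).

The stepwise commands (`simulate`, `build-episodes`, `extract-features`,
`impute`, `fit`, `evaluate`, `surveil`) expose the same stages individually;
see `drainsurv <command> --help`.

## Design notes

See `docs/methods.md` for the statistical methods, the synthetic cohort's
calibration targets and its known simplifications.
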