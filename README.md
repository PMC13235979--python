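# puprev

Positive-unlabeled (PU) prevalence estimation for undercoded phenotypes in
EHR-like data. Given a sparse binary record-by-covariate matrix in which
only some true positives carry a label (1 = coded positive, 0 = unlabeled),
the package estimates what fraction of the unlabeled records is actually
positive, calibrates per-record probabilities, and anchors the final
prevalence to a small expert chart-review audit.

## Pipeline

1. **`puprev.synthetic`** — synthetic PU cohorts with latent positive
   subtypes and either constant (SCAR) or subtype-dependent (SNAR)
   labeling propensity; provides ground truth for parameter-recovery tests.
2. **`puprev.pu_alpha`** — SCAR class-prior estimation: the unlabeled set
   is split into `k = floor(|U|/|P|)` balanced partitions, each paired
   with all labeled positives, scored out-of-fold with a gradient-boosted
   classifier, and the prior is read off the score densities as the
   minimum density ratio; the final estimate averages the partitions.
3. **`puprev.snar`** — SNAR extension: cluster labeled positives into
   subtypes on the gain-positive covariates, run the SCAR estimator per
   cluster, sum the per-cluster priors (capped at 1), and combine
   per-cluster probabilities after anchoring each to its own prior.
4. **`puprev.calibration`** — chart-review audit design (one case per 1%
   probability bin), bias-only logit-shift calibration solved by
   root-finding, percentile bootstrap CI, and extrapolation to the full
   unlabeled population.
5. **`puprev.agreement`** — percent agreement, Cohen/Fleiss kappa (with
   large-sample z), risk-category stratification with a Monte-Carlo
   Fisher exact test, and classification metrics against consensus.
6. **`puprev.reporting` / `puprev.dataio`** — odds ratios, proportion
   CIs, prevalence assembly, and MatrixMarket/TSV/JSON I/O.

## CLI

```bash
puprev simulate --config config.yaml --out cohort/ --seed 1
puprev estimate --method pulsnar --data cohort/ --out est/ --seed 1 --profile test
puprev review-sample --probs est/calibrated_probs.tsv --bin-width 0.01 --seed 1
puprev calibrate --probs est/calibrated_probs.tsv --ratings ratings.tsv --B 100000 --seed 1
puprev agree --ratings ratings.tsv --probs est/calibrated_probs.tsv --threshold 0.5 --seed 1
puprev report --alpha est/alpha.json --calibration calibration.json --counts 1329120,24625
```

`config.yaml` for `simulate` holds `SyntheticConfig` fields
(`n_records`, `n_covariates`, `true_alpha`, `coded_fraction`,
`n_subtypes`, `label_propensities`, `n_informative`, `baseline_rate`,
`lift`). The ratings TSV has columns `record_id`, `rater_*`, and
optionally `consensus`.

## Notes

- The gradient-boosted classifier is scikit-learn's
  `HistGradientBoostingClassifier` behind a config that mirrors the
  XGBoost-style hyperparameters (`max_depth`, `n_estimators`,
  `learning_rate`, feature subsampling); `ClassifierConfig.test_profile()`
  is the reduced desk-scale profile used in tests.
- The min-density-ratio prior estimator uses a Poisson upper envelope on
  the unlabeled density (`ucb_z`), a support floor (`tau`), and coarse
  auto bins; all are exposed on `ClassifierConfig`.
- All outputs are plain text (MTX/TSV/JSON) with deterministic
  formatting.
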