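# thyverify

Diagnostic performance and clinical utility of binary thyroid molecular
classifiers in **partially verified** real-world cohorts.

Thyroid nodules with indeterminate cytology (Bethesda III/IV) are
increasingly triaged with molecular tests before surgery. Evaluating such
a test in routine care runs into verification bias: histopathology — the
reference standard — exists only for operated nodules, and surgery is
driven by the test itself (≈90% of test-positives operated, ≈5% of
test-negatives). The operated-only 2×2 then wildly misstates performance.
`thyverify` implements the whole analysis pipeline used in this study
class, for biostatisticians and clinical researchers evaluating rule-in /
rule-out classifiers:

- a validated nodule-level cohort model (CSV in/out), exclusion rules,
  flow counts, stratified descriptives and histology-subtype tables;
- exact small-sample statistics: Clopper–Pearson intervals, Fisher's
  exact test, Pearson chi-square (with Yates correction);
- the sensitivity-anchored imputation of unoperated test-negatives: with
  external sensitivity Se_ext, `fn_imputed = round(n·(1−Se_ext))`,
  `tn_imputed = n − fn_imputed`, giving an adjusted 2×2 from which
  sensitivity, specificity, PPV, NPV = TN/(TN+FN), accuracy and prevalence
  are computed with exact intervals — always reported side by side with
  the naive operated-only estimates;
- counterfactual utility metrics: decision-support concordance, surgeries
  avoided, and potentially-unnecessary (benign) surgeries avoided;
- a seeded synthetic cohort generator with the same selection structure,
  plus a Monte-Carlo harness comparing naive vs adjusted estimators
  against generative truth.

## Worked example

The package ships a deterministic study-replica cohort
(`data/study_replica.csv`, also constructible via
`thyverify.study_replica_cohort()`): 256 synthetic records whose tallied
margins exactly match a published real-world validation cohort of an
miRNA-based classifier.

```sh
thyverify analyze --input src/thyverify/data/study_replica.csv --out out/
```

The diagnostic-performance section of `out/report.md` reads:

```
| Metric      | Naive (operated only)   | Adjusted (imputed negatives) |
| ----------- | ----------------------- | ---------------------------- |
| sensitivity | 96.1 (86.5-99.5) [49/51] | 83.0 (71.0-91.6) [49/59]    |
| specificity | 14.7 (4.9-31.1) [5/34]   | 83.5 (77.2-88.7) [147/176]  |
| ppv         | 62.8 (51.1-73.5) [49/78] | 62.8 (51.1-73.5) [49/78]    |
| npv         | 71.4 (29.0-96.3) [5/7]   | 93.6 (88.6-96.9) [147/157]  |
| accuracy    | 63.5 (52.4-73.7) [54/85] | 83.4 (78.0-87.9) [196/235]  |
| prevalence  | 60.0 (48.8-70.5) [51/85] | 25.1 (19.7-31.2) [59/235]   |

Adjusted 2x2 - TP: 49, FP: 29, FN: 8 imputed + 2 observed (10),
TN: 142 imputed + 5 observed (147).
```

Read the two columns together: among operated nodules alone the test
looks almost perfectly sensitive (49/51) but uselessly unspecific (5/34)
at an apparent 60% prevalence — artefacts of operating almost only on
positives. After imputing the 150 unoperated negatives with the external
sensitivity 0.946 (142 theoretical benign, 8 theoretical malignant), the
adjusted table gives sensitivity 83.0%, specificity 83.5%, NPV 93.6% at a
25.1% prevalence. The utility section reports 95.5% / 89.8% / 93.5%
decision concordance, 150/236 = 63.6% surgeries avoided, and 140/176 =
79.5% potentially unnecessary surgeries avoided. `out/report.json`
carries the same numbers at full precision with observed/imputed cell
provenance.

A synthetic cohort with the same selection structure, and a bias study:

```sh
thyverify simulate --seed 1 --out sim/ --bias-reps 200
```

`sim/bias_study.json` summarises, per estimator, mean bias, RMSE and CI
coverage against the generative truth — showing the naive operated-only
specificity biased by tens of points while the adjusted estimator tracks
the truth.

Library use mirrors the CLI:

```python
from thyverify import (load_study_replica, apply_exclusions, tally_verified,
                       adjust_counts, compute_performance, AdjustmentConfig)

cohort, log = apply_exclusions(load_study_replica())
adjusted = adjust_counts(tally_verified(cohort), AdjustmentConfig(external_sensitivity=0.946))
print(compute_performance(adjusted).npv)   # 147/157, CI (0.886, 0.969)
```

See `docs/methods.md` for the model, assumptions, rounding conventions
and known limitations (including why the adjusted NPV is a conservative
approximation rather than a true Bayes posterior).

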