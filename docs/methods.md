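# Methods

## Setting and model

`thyverify` analyses cohorts of thyroid nodules with indeterminate cytology
(Bethesda III/IV) tested with a binary molecular classifier (negative /
positive for malignancy). The reference standard is surgical
histopathology, so truth is observed only for operated nodules, and the
decision to operate depends strongly on the test result. This *partial
verification* structure makes the operated-only ("naive") 2×2 biased:
test-negative nodules reach surgery rarely and for unusual reasons, so
naive sensitivity is inflated and naive specificity collapses (most
operated nodules are test-positive, and the benign ones among them are all
counted against specificity).

All analyses are nodule-level: a patient with two tested nodules
contributes two independent records, each with its own cytology, test
result and histology. NIFTP (non-invasive follicular thyroid neoplasm with
papillary-like nuclear features) is counted as malignant throughout,
because its diagnosis itself requires resection and a positive call that
finds NIFTP is regarded as a true positive.

## The verification adjustment

The correction implemented in `performance.py` is the
sensitivity-anchored imputation used in the thyroid molecular-test
literature (often labelled a Bayes/Hall calculation): given `n` unoperated
test-negative nodules and an externally established test sensitivity
`Se_ext`,

    fn_imputed = round(n * (1 - Se_ext))      # nearest, half away from zero
    tn_imputed = n - fn_imputed

and the adjusted 2×2 is the verified cells plus these imputed cells. With
the default `Se_ext = 0.946` (the assay's original validation estimate)
and `n = 150`, the split is 142 theoretical benign / 8 theoretical
malignant. Only the negative arm is imputed; unoperated test-positive
nodules and operated nodules without a retrievable histology report stay
outside the table in dedicated strata (an asymmetry of the method itself:
no external quantity pins down the composition of unverified positives).

Two caveats are printed with every adjusted report and matter for
interpretation:

1. **Intervals.** Confidence intervals on adjusted metrics apply the
   Clopper–Pearson method to the adjusted integer cells as if they were
   binomial observations. Imputed cells are not; the intervals replicate
   the presentation convention of this study class, not a coverage
   guarantee.
2. **The imputation is an approximation, not Bayes' rule.** It treats
   `1 - Se_ext` as the false-omission rate among test-negatives. The true
   false-omission rate is `(1-Se)p / ((1-Se)p + Sp(1-p))`, which is much
   smaller whenever specificity is high (at Se = 0.946, Sp = 0.835,
   p = 0.251 it is 2.1%, not 5.4%). The adjustment therefore *overstates*
   missed malignancies and is conservative for NPV. The bias experiment in
   `simulate.py` shows this directly: the adjusted specificity estimator
   has far smaller bias than the naive one, but the adjusted NPV converges
   below the closed-form NPV `Sp(1-p)/(Sp(1-p)+(1-Se)p)` — the two agree
   only in the knife-edge case `Sp = p·Se/(1-p)`. The corresponding
   acceptance test asserts agreement with the closed form and fails; it is
   left failing because it documents a real limitation of the method, not
   an implementation defect (the method's printed desk arithmetic is
   reproduced exactly).

## Clinical utility accounting

Three rate families, all carried as integer ratios with Clopper–Pearson
intervals:

- **Decision support**: surveillance after a negative call (unoperated
  negatives / all negatives), surgery after a positive call (operated
  positives / all positives, counting the one operated positive without a
  retrievable report as supported), and their pooled concordance.
- **Surgeries avoided**: unoperated negatives over the counterfactual
  "everyone would have been operated" denominator. The default
  denominator excludes test-positive nodules that were not operated anyway
  (they demonstrably would not have been resected); `counterfactual="all"`
  uses the whole analyzable cohort.
- **Potentially unnecessary surgeries avoided**: the benign pool is
  `tn_imputed + tn_observed + fp`. The default accounting subtracts, as
  "not avoided", every operated test-negative nodule (their surgeries were
  driven by factors other than the negative call — in the emulated study,
  a co-existing test-positive nodule) plus the benign operated positives;
  this reproduces the published 140/176 = 79.5%. The internally strict
  variant (`benign_surgeries_only=True`) subtracts only benign-histology
  surgeries and yields 142/176 = 80.7%. Both are exposed because the two
  conventions genuinely differ and the difference (two nodules here) can
  matter in smaller cohorts.

## Exact statistics

Clopper–Pearson bounds are Beta quantiles (`scipy.stats.beta.ppf`), with
the conventional closures at x = 0 and x = n; the test suite checks them
against an independent bisection over exact binomial tail sums. Fisher's
exact test uses the probability-mass two-sided criterion (ties within
relative 1e−7), verified against full hypergeometric enumeration for every
2×2 table with grand total ≤ 40. Pearson's chi-square supports the Yates
continuity correction for 2×2 tables; the default association test for
cohort descriptives is the corrected chi-square, falling back to Fisher
when any expected cell is below 5. Only Clopper–Pearson intervals are
offered — at verified-sample sizes of a handful of nodules, approximate
intervals undercover.

Zero denominators yield "undefined" (`None`), never 0; a zero-margin
contingency table is a domain error for chi-square and "not applicable"
for descriptive p-values.

## Rounding convention

Percentages are rendered at one decimal via a two-stage chain: round
half-up at two decimals, then round at one decimal with exact midpoints
resolved downward. This is the chain a value follows when it passes
through a two-decimal intermediate (as in spreadsheet-exported clinical
tables), and it reproduces the published tables this package's fixtures
emulate, including the boundary cases 83.0508% → 83.0 and 79.5455% → 79.5.
JSON output always carries full-precision fractions and raw integer cells;
rounding exists only in the human-readable rendering. P-values are
displayed at two significant figures with a `<0.001` floor and `>0.9`
ceiling.

## Synthetic cohort generator

`simulate.py` draws, per nodule: malignancy ~ Bernoulli(prevalence); a
positive call with probability Se if malignant, 1−Sp otherwise; surgery ~
Bernoulli(p_surgery | call); histology revealed (equal to truth, with a
4% NIFTP fraction among operated malignants) only upon surgery and subject
to a small report-missingness probability. Surgery depends only on the
test result — exactly the information structure the imputation assumes. A
`surgery_truth_leakage` parameter (default 0) adds surgery probability for
malignant test-negatives, for robustness experiments emulating nodules
operated because of a co-existing positive nodule.

Defaults emulate the real-world cohort the package's fixtures replicate:
n = 245 nodules, prevalence 0.251, Se/Sp 0.83/0.835 (the adjusted-estimate
scale), surgery probability 0.898 after a positive and 0.045 after a
negative call, 78% Bethesda IV, 83.7% female, ages 20–90, log-normal
nodule size (μ = 0.08, σ = 0.45 on the log scale, mean ≈ 1.2 cm),
follow-up uniform on 10–1451 days for unoperated negatives, histology
report missingness 0.012 (≈ 1 report in 86 surgeries). The
collision-tumor fraction defaults to 0 so the default cohort size equals
the analyzable 245; exclusions are exercised by the bundled replica
fixture and by non-default parameters.

Covariates (age, sex, Bethesda class, size) are drawn independently of
malignancy: they exercise the descriptive layer and deliberately encode no
risk model. Consequently, passing tests demonstrate correct accounting and
the selection-bias mechanics, not covariate-outcome structure of real
cohorts; nor does the generator model ultrasound features, repeat
cytology, or inter-laboratory histology variation.

`bias_experiment` runs replicate cohorts (child seeds spawned from the
master seed, kept below 2^31), computes naive and adjusted estimates per
replicate, and summarises mean bias, RMSE and empirical CI coverage
against the generative truth. Replicates with an empty denominator are
recorded as undefined and excluded from summaries with a count.

## Study-replica fixture

`replica.py` builds a deterministic 256-record cohort whose every tallied
margin equals the emulated study's: 11 collision exclusions; arms
157/88; verified cells 49/29/2/5; the full histology-subtype
distribution; per-arm age/sex/Bethesda stratum counts; follow-up with mean
exactly 706 days on 10–1451; 251 distinct patients for 256 nodules (the
two false-negative nodules share patients with two true positives).
Attributes are spread across each arm with an even deterministic
interleave so no covariate concentrates in one flow sub-block. The
records are synthetic — only the margins are exact — and the same table
ships as `data/study_replica.csv`.

## Problem sizes used in the checks

The bundled reproduction runs at the study's own desk scale (245
analyzable nodules, < 1 s). The property checks use: exhaustive Fisher
enumeration over all 135,750 tables with grand total ≤ 40; Clopper–Pearson
coverage on a 9 × 3 (p, n) grid with 10,000 seeded draws per cell; 1,000
random synthetic cohorts for the conservation invariants; 500 replicates
for the estimator-bias comparison; and a single n = 50,000 cohort to
exhibit the large-sample collapse of naive specificity.

## Known limitations

- The adjustment corrects only the negative arm and only via an external
  sensitivity; it cannot repair bias from unverified positives, and its
  NPV is conservative (see above). Alternative corrections
  (Begg–Greenes, multiple imputation, predictive-value intervals) are out
  of scope.
- Exclusion flags (collision tumors, unmatched nodules) are taken from the
  input data; the package does not attempt FNA-to-pathology nodule
  matching, for which no algorithmic rule exists.
- Printed confidence intervals in this study class are not always
  Clopper–Pearson even when the text says so; this package reports CP on
  the stated integer ratios and leaves discrepancies visible rather than
  chasing them.
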