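"""Synthetic cohort generator and Monte-Carlo bias experiments.

The generator reproduces the *selection structure* of a partially verified
diagnostic cohort: a latent malignancy status per nodule, an imperfect
binary classifier, a surgery decision that depends only on the classifier
output, and a reference standard (histology) revealed only upon surgery.
That structure — not the covariates — is what makes naive operated-only
accuracy estimates biased, and it is exactly what the imputation in
:mod:`thyverify.performance` targets; the bias experiment here measures
both estimators against the generative truth.

Covariates (age, sex, Bethesda class, nodule size) are drawn independently
of malignancy: they exercise the descriptive layer and carry no risk
signal.  Default parameters emulate a real-world indeterminate-nodule
cohort: n = 245, prevalence 0.251, surgery probability 0.898 after a
positive and 0.045 after a negative call, 78% Bethesda IV, 83.7% female.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import (
    Bethesda,
    CohortTable,
    ExclusionFlag,
    Histology,
    NoduleRecord,
    Sex,
    TestResult,
)
from .performance import (
    AdjustmentConfig,
    adjust_counts,
    compute_performance,
    tally_verified,
)

__all__ = ["SimulationParams", "BiasStudyResult", "default_params", "simulate_cohort", "bias_experiment"]

_BENIGN_SUBTYPES = (
    ("Follicular adenoma", 0.72),
    ("Thyroid follicular nodular disease", 0.14),
    ("Oncocytic adenoma of the thyroid", 0.07),
    ("Thyroiditis", 0.07),
)
_MALIGNANT_SUBTYPES = (
    ("Papillary thyroid micro/carcinoma variant follicular", 0.78),
    ("Follicular thyroid carcinoma minimally invasive", 0.08),
    ("Papillary thyroid micro/carcinoma classic", 0.06),
    ("Papillary thyroid micro/carcinoma subtype solid", 0.03),
    ("Papillary thyroid microcarcinoma subtype oncocytic", 0.03),
    ("Oncocytic microcarcinoma of the thyroid", 0.02),
)


@dataclass(frozen=True)
class SimulationParams:
    """Generative-model parameters for a synthetic cohort.

    ``surgery_truth_leakage`` adds extra surgery probability for malignant
    test-negative nodules (default 0: surgery depends on the test result
    only, the information structure the imputation assumes).  ``size_mu`` /
    ``size_sigma`` are log-normal location/scale of nodule size in cm.
    """

    n_nodules: int = 245
    prevalence: float = 0.251
    test_sensitivity: float = 0.83
    test_specificity: float = 0.835
    p_surgery_given_positive: float = 0.898
    p_surgery_given_negative: float = 0.045
    p_histology_missing_given_surgery: float = 0.012
    niftp_fraction: float = 0.04
    bethesda_iv_fraction: float = 0.78
    female_fraction: float = 0.837
    age_range: tuple[int, int] = (20, 90)
    size_mu: float = 0.08
    size_sigma: float = 0.45
    collision_fraction: float = 0.0
    followup_days_range: tuple[int, int] = (10, 1451)
    surgery_truth_leakage: float = 0.0
    multi_nodule_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = {
            "prevalence": self.prevalence,
            "test_sensitivity": self.test_sensitivity,
            "test_specificity": self.test_specificity,
            "p_surgery_given_positive": self.p_surgery_given_positive,
            "p_surgery_given_negative": self.p_surgery_given_negative,
            "p_histology_missing_given_surgery": self.p_histology_missing_given_surgery,
            "niftp_fraction": self.niftp_fraction,
            "bethesda_iv_fraction": self.bethesda_iv_fraction,
            "female_fraction": self.female_fraction,
            "collision_fraction": self.collision_fraction,
            "surgery_truth_leakage": self.surgery_truth_leakage,
            "multi_nodule_fraction": self.multi_nodule_fraction,
        }
        for name, v in fractions.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_nodules < 0:
            raise ValueError("n_nodules must be >= 0")
        if self.age_range[0] < 18 or self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must satisfy 18 <= min <= max")
        if self.followup_days_range[0] < 0 or self.followup_days_range[0] > self.followup_days_range[1]:
            raise ValueError("followup_days_range must satisfy 0 <= min <= max")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["age_range"] = list(self.age_range)
        d["followup_days_range"] = list(self.followup_days_range)
        return d


@dataclass(frozen=True)
class BiasStudyResult:
    """Per-replicate naive vs adjusted estimates and their summary errors.

    ``per_replicate`` has one row per replicate with columns
    ``{naive,adjusted}_{sensitivity,specificity,npv}`` (NaN where a
    denominator was empty); ``summary`` maps each estimator to its mean
    bias, RMSE and empirical CI coverage against the generative truth.
    """

    per_replicate: pd.DataFrame
    summary: dict
    truth: dict
    params: SimulationParams
    external_sensitivity: float
    n_replicates: int
    n_excluded: dict
    seed: int


def default_params(seed: int = 0) -> SimulationParams:
    """The study-emulating parameter set (see module docstring)."""
    return SimulationParams(seed=seed)


def expected_positive_rate(params: SimulationParams) -> float:
    """Closed-form marginal probability of a positive call."""
    return (
        params.prevalence * params.test_sensitivity
        + (1.0 - params.prevalence) * (1.0 - params.test_specificity)
    )


def simulate_cohort(params: SimulationParams) -> CohortTable:
    """Draw one cohort; identical params (incl. seed) give identical output.

    Per nodule: truth ~ Bernoulli(prevalence); positive call with
    probability Se if malignant else 1 - Sp; surgery ~ Bernoulli(p_surgery
    given the call, plus leakage if malignant and negative); histology
    equals truth when operated and the report is retrievable (a
    ``niftp_fraction`` of operated malignants is recorded as NIFTP), else
    unavailable.  Follow-up days are drawn for unoperated test-negatives
    only, mirroring how follow-up is defined for surveillance patients.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_nodules
    records: list[NoduleRecord] = []
    shared_with_prev = rng.random(n) < params.multi_nodule_fraction
    patient_counter = 0
    for i in range(n):
        malignant = rng.random() < params.prevalence
        p_pos = params.test_sensitivity if malignant else 1.0 - params.test_specificity
        positive = rng.random() < p_pos
        p_surg = (
            params.p_surgery_given_positive if positive else params.p_surgery_given_negative
        )
        if malignant and not positive:
            p_surg = min(1.0, p_surg + params.surgery_truth_leakage)
        surgery = rng.random() < p_surg
        histology = Histology.UNAVAILABLE
        subtype = None
        if surgery and rng.random() >= params.p_histology_missing_given_surgery:
            if malignant:
                if rng.random() < params.niftp_fraction:
                    histology, subtype = Histology.NIFTP, "NIFTP"
                else:
                    histology = Histology.MALIGNANT
                    subtype = _choice(rng, _MALIGNANT_SUBTYPES)
            else:
                histology = Histology.BENIGN
                subtype = _choice(rng, _BENIGN_SUBTYPES)
        followup = None
        if not surgery and not positive:
            lo, hi = params.followup_days_range
            followup = int(rng.integers(lo, hi + 1))
        age = int(rng.integers(params.age_range[0], params.age_range[1] + 1))
        sex = Sex.FEMALE if rng.random() < params.female_fraction else Sex.MALE
        bethesda = Bethesda.IV if rng.random() < params.bethesda_iv_fraction else Bethesda.III
        size = round(float(np.exp(rng.normal(params.size_mu, params.size_sigma))), 2)
        excluded = rng.random() < params.collision_fraction
        if i > 0 and shared_with_prev[i]:
            patient_id = f"SP{patient_counter:04d}"
        else:
            patient_counter += 1
            patient_id = f"SP{patient_counter:04d}"
        records.append(
            NoduleRecord(
                patient_id=patient_id,
                nodule_id=f"SN{i + 1:04d}",
                age_years=age,
                sex=sex,
                bethesda=bethesda,
                test_result=TestResult.POSITIVE if positive else TestResult.NEGATIVE,
                surgery=surgery,
                histology=histology,
                histology_subtype=subtype,
                nodule_size_cm=max(size, 0.1),
                followup_days=followup,
                exclusion_flag=ExclusionFlag.COLLISION_TUMOR if excluded else ExclusionFlag.NONE,
            )
        )
    return CohortTable.from_records(records, provenance=f"simulated(seed={params.seed})")


def _choice(rng: np.random.Generator, table: tuple) -> str:
    names = [t[0] for t in table]
    probs = np.array([t[1] for t in table])
    return names[rng.choice(len(names), p=probs / probs.sum())]


def true_npv(params: SimulationParams) -> float:
    """Closed-form NPV of the generative test: Sp(1-p) / (Sp(1-p) + (1-Se)p)."""
    p, se, sp = params.prevalence, params.test_sensitivity, params.test_specificity
    denom = sp * (1.0 - p) + (1.0 - se) * p
    return sp * (1.0 - p) / denom if denom > 0 else float("nan")


def bias_experiment(
    params: SimulationParams,
    n_replicates: int,
    external_sensitivity: Optional[float] = None,
    confidence: float = 0.95,
) -> BiasStudyResult:
    """Monte-Carlo comparison of naive vs adjusted estimators.

    Each replicate simulates a cohort (exclusion-flagged records dropped),
    tallies it, and computes the naive (operated-only) and adjusted
    performance reports.  ``external_sensitivity`` defaults to the
    generative sensitivity — the best case the correction assumes.
    Replicates with an empty denominator for a metric are NaN there and
    excluded from that metric's summary (counts in ``n_excluded``).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    se_ext = params.test_sensitivity if external_sensitivity is None else external_sensitivity
    cfg = AdjustmentConfig(external_sensitivity=se_ext)
    child_seeds = np.random.SeedSequence(params.seed).generate_state(n_replicates) % (2**31)

    truth = {
        "sensitivity": params.test_sensitivity,
        "specificity": params.test_specificity,
        "npv": true_npv(params),
    }
    metrics = ("sensitivity", "specificity", "npv")
    rows = []
    cover = {f"{mode}_{m}": [] for mode in ("naive", "adjusted") for m in metrics}
    for rep in range(n_replicates):
        rep_params = replace(params, seed=int(child_seeds[rep]))
        cohort = simulate_cohort(rep_params)
        analyzable = [r for r in cohort if r.exclusion_flag is ExclusionFlag.NONE]
        v = tally_verified(CohortTable.from_records(analyzable))
        row = {}
        for mode, counts in (("naive", v), ("adjusted", adjust_counts(v, cfg))):
            try:
                rep_report = compute_performance(counts, confidence)
            except ValueError:
                rep_report = None
            for m in metrics:
                prop = getattr(rep_report, m, None) if rep_report else None
                key = f"{mode}_{m}"
                row[key] = prop.estimate if prop else np.nan
                if prop:
                    cover[key].append(prop.ci.low <= truth[m] <= prop.ci.high)
        rows.append(row)

    per_replicate = pd.DataFrame(rows)
    summary: dict = {}
    n_excluded: dict = {}
    for key in per_replicate.columns:
        vals = per_replicate[key].dropna().to_numpy()
        m = key.split("_", 1)[1]
        n_excluded[key] = int(per_replicate[key].isna().sum())
        if len(vals) == 0:
            summary[key] = None
            continue
        err = vals - truth[m]
        summary[key] = {
            "mean": float(vals.mean()),
            "mean_bias": float(err.mean()),
            "rmse": float(np.sqrt((err**2).mean())),
            "ci_coverage": float(np.mean(cover[key])) if cover[key] else None,
            "n_used": int(len(vals)),
        }
    return BiasStudyResult(
        per_replicate=per_replicate,
        summary=summary,
        truth=truth,
        params=params,
        external_sensitivity=se_ext,
        n_replicates=n_replicates,
        n_excluded=n_excluded,
        seed=params.seed,
    )
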