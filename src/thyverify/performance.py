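"""Verified 2x2 tally, Bayes/Hall imputation of unverified test-negatives,
and diagnostic performance with exact intervals.

In a partially verified cohort the reference standard (surgical histology)
is observed almost only when the test is positive, so the operated-only
("naive") 2x2 is biased: sensitivity is inflated and specificity deflated
(work-up / verification bias).  The correction implemented here takes an
externally established test sensitivity and splits the unoperated
test-negative stratum into theoretical true-benign and missed-malignant
counts — the Bayes-theorem route to the negative predictive value described
by Hall for imaging tests.  Only the negative arm is imputed; unoperated
test-positives never enter the 2x2 (a deliberate asymmetry of the method:
no external quantity pins down their composition).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Union

from .cohort import (
    CohortTable,
    Histology,
    TestResult,
    Truth,
    truth_label,
)
from .exact import Proportion, proportion_with_ci

__all__ = [
    "VerifiedCounts",
    "AdjustmentConfig",
    "AdjustedCounts",
    "PerformanceReport",
    "PerformanceError",
    "tally_verified",
    "impute_unverified_negatives",
    "adjust_counts",
    "compute_performance",
]


log = logging.getLogger("thyverify")


class PerformanceError(ValueError):
    pass


@dataclass(frozen=True)
class VerifiedCounts:
    """Observed cohort tally: the verified 2x2 plus the unverified strata.

    ``tp``/``fp`` are operated test-positives with malignant (incl. NIFTP) /
    benign histology; ``fn_operated``/``tn_operated`` the same for operated
    test-negatives.  The remaining strata never carry a truth label:
    unoperated nodules by arm, and operated nodules whose histology report
    was unavailable (kept in dedicated strata so the cohort always sums).
    """

    tp: int
    fp: int
    fn_operated: int
    tn_operated: int
    n_negative_unoperated: int
    n_positive_unoperated: int
    n_positive_no_histology: int = 0
    n_negative_no_histology: int = 0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def total(self) -> int:
        return sum(self.__dict__.values())

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class AdjustmentConfig:
    """How to impute the unoperated test-negative stratum.

    ``external_sensitivity`` is the test sensitivity established outside
    this cohort (default 0.946, the assay's original validation estimate);
    ``rounding`` controls how the fractional expected miss count becomes an
    integer cell (nearest = half away from zero).
    """

    external_sensitivity: float = 0.946
    rounding: str = "nearest"

    def __post_init__(self) -> None:
        if not (0.0 < self.external_sensitivity <= 1.0):
            raise ValueError("external_sensitivity must be in (0, 1]")
        if self.rounding not in ("nearest", "floor", "ceiling"):
            raise ValueError("rounding must be one of: nearest, floor, ceiling")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class AdjustedCounts:
    """The 2x2 after imputation, with observed/imputed provenance kept apart."""

    tp: int
    fp: int
    fn_observed: int
    fn_imputed: int
    tn_observed: int
    tn_imputed: int

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def fn_total(self) -> int:
        return self.fn_observed + self.fn_imputed

    @property
    def tn_total(self) -> int:
        return self.tn_observed + self.tn_imputed

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn_total + self.tn_total

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["fn_total"] = self.fn_total
        d["tn_total"] = self.tn_total
        return d


@dataclass(frozen=True)
class PerformanceReport:
    """Six diagnostic metrics, each an exact-interval Proportion.

    A metric whose denominator is zero is ``None`` (undefined), never 0.
    ``mode`` records whether the 2x2 was the operated-only table ("naive")
    or the imputation-augmented one ("adjusted").  The intervals on
    adjusted metrics treat imputed cells as if they were binomial
    observations — replicating the presentation convention of the source
    method, not a claim of exact coverage; reports carry this caveat.
    """

    sensitivity: Optional[Proportion]
    specificity: Optional[Proportion]
    ppv: Optional[Proportion]
    npv: Optional[Proportion]
    accuracy: Optional[Proportion]
    prevalence: Optional[Proportion]
    mode: str
    confidence: float = 0.95

    _METRICS = ("sensitivity", "specificity", "ppv", "npv", "accuracy", "prevalence")

    def to_dict(self) -> dict:
        d = {m: (getattr(self, m).to_dict() if getattr(self, m) else None) for m in self._METRICS}
        d["mode"] = self.mode
        d["confidence"] = self.confidence
        d["caveat"] = (
            "Intervals on adjusted metrics apply the exact binomial method to "
            "imputed integer cells, which are not true binomial observations."
            if self.mode == "adjusted"
            else None
        )
        return d


def tally_verified(cohort: CohortTable) -> VerifiedCounts:
    """Tally a post-exclusion cohort into the verified 2x2 and unverified strata.

    Every record lands in exactly one stratum; NIFTP counts as malignant.
    Operated records without an accessible histology report go to the
    per-arm no-histology strata (and are logged): they never enter a 2x2
    cell.
    """
    tp = fp = fn = tn = neg_unop = pos_unop = pos_nohist = neg_nohist = 0
    for r in cohort:
        positive = r.test_result is TestResult.POSITIVE
        if not r.surgery:
            if positive:
                pos_unop += 1
            else:
                neg_unop += 1
            continue
        if r.histology is Histology.UNAVAILABLE:
            if positive:
                pos_nohist += 1
            else:
                neg_nohist += 1
                log.info(
                    "operated test-negative nodule %s has no histology report; "
                    "counted in a dedicated stratum outside the 2x2",
                    r.nodule_id,
                )
            continue
        malignant = truth_label(r) is Truth.MALIGNANT
        if positive:
            tp, fp = tp + malignant, fp + (not malignant)
        else:
            fn, tn = fn + malignant, tn + (not malignant)
    return VerifiedCounts(
        tp=tp,
        fp=fp,
        fn_operated=fn,
        tn_operated=tn,
        n_negative_unoperated=neg_unop,
        n_positive_unoperated=pos_unop,
        n_positive_no_histology=pos_nohist,
        n_negative_no_histology=neg_nohist,
    )


def impute_unverified_negatives(
    n_unoperated_negative: int, cfg: AdjustmentConfig = AdjustmentConfig()
) -> tuple[int, int]:
    """Split n unverified test-negatives into (tn_imputed, fn_imputed).

    The expected number of missed malignancies among n test-negatives is
    n * (1 - Se_ext); it is converted to an integer cell under
    ``cfg.rounding`` and the remainder is counted benign.
    """
    n = int(n_unoperated_negative)
    if n < 0:
        raise ValueError("n_unoperated_negative must be >= 0")
    expected_fn = n * (1.0 - cfg.external_sensitivity)
    if cfg.rounding == "nearest":
        fn = math.floor(expected_fn + 0.5)  # half away from zero (n >= 0)
    elif cfg.rounding == "floor":
        fn = math.floor(expected_fn)
    else:
        fn = math.ceil(expected_fn)
    fn = min(max(fn, 0), n)
    return n - fn, fn


def adjust_counts(
    v: VerifiedCounts, cfg: AdjustmentConfig = AdjustmentConfig()
) -> AdjustedCounts:
    """Build the imputation-augmented 2x2 from the verified tally.

    Observed cells are copied; the unoperated-negative stratum is imputed.
    Unoperated positives and operated no-histology records stay outside the
    table.
    """
    tn_imp, fn_imp = impute_unverified_negatives(v.n_negative_unoperated, cfg)
    return AdjustedCounts(
        tp=v.tp,
        fp=v.fp,
        fn_observed=v.fn_operated,
        fn_imputed=fn_imp,
        tn_observed=v.tn_operated,
        tn_imputed=tn_imp,
    )


def compute_performance(
    counts: Union[AdjustedCounts, VerifiedCounts], confidence: float = 0.95
) -> PerformanceReport:
    """Sensitivity, specificity, PPV, NPV, accuracy and prevalence with exact CIs.

    Pass :class:`AdjustedCounts` for the imputation-adjusted table or
    :class:`VerifiedCounts` for the naive operated-only table (its
    unverified strata are ignored).  Each metric gets a Clopper-Pearson
    interval on its own (numerator, denominator); a zero-denominator metric
    is reported as ``None``.
    """
    if isinstance(counts, AdjustedCounts):
        tp, fp, fn, tn = counts.tp, counts.fp, counts.fn_total, counts.tn_total
        mode = "adjusted"
    elif isinstance(counts, VerifiedCounts):
        tp, fp, fn, tn = counts.tp, counts.fp, counts.fn_operated, counts.tn_operated
        mode = "naive"
    else:
        raise TypeError("counts must be AdjustedCounts or VerifiedCounts")
    n = tp + fp + fn + tn
    if n == 0:
        raise PerformanceError("no verified outcomes: all 2x2 cells are zero")

    def prop(x: int, d: int) -> Optional[Proportion]:
        return proportion_with_ci(x, d, confidence) if d > 0 else None

    return PerformanceReport(
        sensitivity=prop(tp, tp + fn),
        specificity=prop(tn, tn + fp),
        ppv=prop(tp, tp + fp),
        npv=prop(tn, tn + fn),
        accuracy=prop(tp + tn, n),
        prevalence=prop(tp + fn, n),
        mode=mode,
        confidence=confidence,
    )
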