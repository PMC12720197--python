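"""Decision-support concordance and counterfactual surgery-avoidance rates.

The clinical value of a rule-out classifier in indeterminate thyroid
nodules is measured here in three ways: how often management followed the
test (surveillance after a negative call, surgery after a positive call);
how many surgeries were avoided against the counterfactual that every
nodule would have been resected absent testing; and how many *potentially
unnecessary* surgeries (on ultimately benign nodules, observed or imputed)
were avoided.  All rates are ratios of integer counts carried as
:class:`~thyverify.exact.Proportion` with Clopper-Pearson intervals,
treating each rate as a binomial proportion — the convention of this class
of study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .cohort import FlowCounts
from .exact import Proportion, proportion_with_ci
from .performance import AdjustedCounts, AdjustmentConfig

__all__ = [
    "UtilityReport",
    "decision_support",
    "surgeries_avoided",
    "potentially_unnecessary_avoided",
    "utility_report",
]

COUNTERFACTUAL_EXCLUDE = "exclude-unoperated-positives"
COUNTERFACTUAL_ALL = "all"


@dataclass(frozen=True)
class UtilityReport:
    """The utility rates plus the counterfactual assumptions that produced them."""

    support_when_negative: Optional[Proportion]
    support_when_positive: Optional[Proportion]
    overall_concordance: Optional[Proportion]
    surgeries_avoided: Optional[Proportion]
    potentially_unnecessary_avoided: Optional[Proportion]
    assumptions: dict

    def __post_init__(self) -> None:
        if (
            self.support_when_negative
            and self.support_when_positive
            and self.overall_concordance
        ):
            if self.overall_concordance.numerator != (
                self.support_when_negative.numerator + self.support_when_positive.numerator
            ):
                raise ValueError("concordance numerator must be the sum of the arm numerators")

    def to_dict(self) -> dict:
        def d(p):
            return p.to_dict() if p else None

        return {
            "support_when_negative": d(self.support_when_negative),
            "support_when_positive": d(self.support_when_positive),
            "overall_concordance": d(self.overall_concordance),
            "surgeries_avoided": d(self.surgeries_avoided),
            "potentially_unnecessary_avoided": d(self.potentially_unnecessary_avoided),
            "assumptions": dict(self.assumptions),
        }


def decision_support(
    f: FlowCounts, confidence: float = 0.95
) -> tuple[Optional[Proportion], Optional[Proportion], Optional[Proportion]]:
    """Concordance of management with the test result, per arm and overall.

    A negative call supports surveillance (numerator: unoperated negatives);
    a positive call supports surgery (numerator: operated positives, with or
    without a retrievable histology report).  A zero arm leaves that rate
    undefined (``None``).
    """
    if f.n_analyzable <= 0:
        raise ValueError("decision_support requires a non-empty cohort")
    neg = (
        proportion_with_ci(f.n_negative_unoperated, f.n_test_negative, confidence)
        if f.n_test_negative > 0
        else None
    )
    pos = (
        proportion_with_ci(f.n_positive_operated, f.n_test_positive, confidence)
        if f.n_test_positive > 0
        else None
    )
    overall = proportion_with_ci(
        f.n_negative_unoperated + f.n_positive_operated, f.n_analyzable, confidence
    )
    return neg, pos, overall


def surgeries_avoided(
    f: FlowCounts,
    confidence: float = 0.95,
    counterfactual: str = COUNTERFACTUAL_EXCLUDE,
) -> Proportion:
    """Fraction of counterfactual surgeries avoided thanks to negative calls.

    The counterfactual assumes every nodule would have been resected had no
    molecular test existed.  By default the denominator excludes test-positive
    nodules whose surgery did not happen anyway (they demonstrably would not
    have been operated); ``counterfactual="all"`` uses the whole analyzable
    cohort instead (a stricter, non-default accounting).
    """
    if counterfactual == COUNTERFACTUAL_EXCLUDE:
        denom = f.n_analyzable - f.n_positive_unoperated
    elif counterfactual == COUNTERFACTUAL_ALL:
        denom = f.n_analyzable
    else:
        raise ValueError(f"unknown counterfactual {counterfactual!r}")
    if denom <= 0:
        raise ValueError("counterfactual denominator must be positive")
    return proportion_with_ci(f.n_negative_unoperated, denom, confidence)


def potentially_unnecessary_avoided(
    a: AdjustedCounts,
    f: Optional[FlowCounts] = None,
    confidence: float = 0.95,
    benign_surgeries_only: bool = False,
) -> Optional[Proportion]:
    """Fraction of potentially unnecessary surgeries (benign nodules) avoided.

    The benign pool is ``tn_imputed + tn_observed + fp``: imputed-benign
    unoperated negatives, operated benign negatives, and operated benign
    positives.  From it the performed surgeries are subtracted.  The default
    accounting subtracts every operated test-negative nodule (benign or
    malignant at histology — their surgeries were driven by factors other
    than this nodule's negative call) plus the benign operated positives;
    with ``benign_surgeries_only=True`` only benign-histology surgeries
    (``tn_observed + fp``) are subtracted, which is the internally strict
    variant.  Requires ``f`` (flow counts) for the default accounting, to
    know the total number of operated test-negative nodules.

    Returns ``None`` when the benign pool is empty.
    """
    benign_total = a.tn_imputed + a.tn_observed + a.fp
    if benign_total == 0:
        return None
    if benign_surgeries_only:
        operated = a.tn_observed + a.fp
    else:
        n_negative_operated = f.n_negative_operated if f is not None else (
            a.tn_observed + a.fn_observed
        )
        operated = n_negative_operated + a.fp
    avoided = benign_total - operated
    if avoided < 0:
        raise ValueError("operated count exceeds the benign pool; check inputs")
    return proportion_with_ci(avoided, benign_total, confidence)


def utility_report(
    f: FlowCounts,
    a: AdjustedCounts,
    cfg: AdjustmentConfig,
    confidence: float = 0.95,
    counterfactual: str = COUNTERFACTUAL_EXCLUDE,
    benign_surgeries_only: bool = False,
) -> UtilityReport:
    """Assemble the full utility report with an explicit assumptions block."""
    neg, pos, overall = decision_support(f, confidence)
    return UtilityReport(
        support_when_negative=neg,
        support_when_positive=pos,
        overall_concordance=overall,
        surgeries_avoided=surgeries_avoided(f, confidence, counterfactual),
        potentially_unnecessary_avoided=potentially_unnecessary_avoided(
            a, f, confidence, benign_surgeries_only
        ),
        assumptions={
            "counterfactual_denominator": counterfactual,
            "unnecessary_accounting": (
                "benign-histology surgeries only"
                if benign_surgeries_only
                else "all operated test-negatives plus benign operated positives"
            ),
            "imputation": cfg.to_dict(),
            "confidence": confidence,
            "operated_positive_without_histology_counts_as_supported": True,
        },
    )
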