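"""End-to-end analysis pipeline and report rendering (JSON + markdown).

``run_analysis`` chains ingestion -> exclusions -> descriptives ->
performance (naive and adjusted, always side by side so the effect of the
imputation is visible) -> clinical utility, and returns a bundle that
serialises to JSON at full precision and renders to markdown with the
1-decimal percentage style of clinical tables.  Every number appearing in
the markdown is also present in the JSON bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

from . import cohort as cm
from . import performance as perf
from . import utility as ut
from .formatting import fmt_percent, fmt_proportion_percent, markdown_table
from .exact import format_p

__all__ = ["RunConfig", "ReportBundle", "AnalysisError", "run_analysis"]

log = logging.getLogger("thyverify")


class AnalysisError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run."""

    input_path: str
    confidence: float = 0.95
    adjustment: perf.AdjustmentConfig = field(default_factory=perf.AdjustmentConfig)
    counterfactual: str = ut.COUNTERFACTUAL_EXCLUDE
    age_cut: int = 54

    def __post_init__(self) -> None:
        if not (0.0 < self.confidence < 1.0):
            raise ValueError("confidence must be in (0, 1)")


@dataclass(frozen=True)
class ReportBundle:
    """Everything one run produces, in machine- and human-readable form."""

    exclusion_log: cm.ExclusionLog
    flow: cm.FlowCounts
    summary: cm.CohortSummary
    histology: "object"  # pandas DataFrame
    verified: perf.VerifiedCounts
    adjusted: perf.AdjustedCounts
    performance_naive: perf.PerformanceReport
    performance_adjusted: perf.PerformanceReport
    utility: ut.UtilityReport
    config: RunConfig

    def to_json_dict(self) -> dict:
        return {
            "exclusion_log": self.exclusion_log.to_dict(),
            "flow_counts": self.flow.to_dict(),
            "cohort_summary": self.summary.to_dict(),
            "histology_table": {
                str(ix): {c: int(v) for c, v in row.items()}
                for ix, row in self.histology.to_dict(orient="index").items()
            },
            "verified_counts": self.verified.to_dict(),
            "adjusted_counts": self.adjusted.to_dict(),
            "performance": {
                "naive": self.performance_naive.to_dict(),
                "adjusted": self.performance_adjusted.to_dict(),
            },
            "utility": self.utility.to_dict(),
            "assumptions": {
                "confidence": self.config.confidence,
                "adjustment": self.config.adjustment.to_dict(),
                "counterfactual_denominator": self.config.counterfactual,
                "age_cut": self.config.age_cut,
                "niftp_counted_malignant": True,
                "analysis_level": "nodule",
            },
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_json_dict(), indent=indent)

    def to_markdown(self) -> str:
        parts = [self._md_flow(), self._md_summary(), self._md_histology(),
                 self._md_performance(), self._md_utility()]
        return "\n\n".join(parts) + "\n"

    # --- markdown sections -------------------------------------------------

    def _md_flow(self) -> str:
        f, e = self.flow, self.exclusion_log
        lines = [
            "## Cohort flow",
            "",
            f"- input records: {e.n_input}",
        ]
        for reason, n in sorted(e.n_excluded_by_reason.items()):
            lines.append(f"- excluded ({reason}): {n}")
        rate = (
            f" ({fmt_percent(f.n_test_positive / f.n_analyzable)}% positive call rate)"
            if f.n_analyzable
            else ""
        )
        lines += [
            f"- analyzable nodules: {f.n_analyzable}",
            f"- test-negative: {f.n_test_negative} "
            f"({f.n_negative_unoperated} unoperated, {f.n_negative_operated} operated)",
            f"- test-positive: {f.n_test_positive}{rate} "
            f"({f.n_positive_unoperated} unoperated, {f.n_positive_operated} operated, "
            f"{f.n_positive_operated_no_histology} without histology report)",
        ]
        return "\n".join(lines)

    def _md_summary(self) -> str:
        s = self.summary
        rows = []
        for name, levels in s.strata.items():
            p = s.pvalues.get(name)
            rows.append([f"**{name}**", "", "", format_p(p) if p is not None else "n/a"])
            for lvl, (n_neg, n_pos) in levels.items():
                pct_n = fmt_percent(n_neg / s.n_test_negative) if s.n_test_negative else "-"
                pct_p = fmt_percent(n_pos / s.n_test_positive) if s.n_test_positive else "-"
                rows.append([lvl, f"{n_neg} ({pct_n})", f"{n_pos} ({pct_p})", ""])
        table = markdown_table(
            ["Variable", f"Negative (n={s.n_test_negative})",
             f"Positive (n={s.n_test_positive})", "P-value"],
            rows,
        )
        extra = [f"Mean age: {s.mean_age_years:.1f} years."]
        if s.mean_nodule_size_cm is not None:
            extra.append(f"Mean nodule size: {s.mean_nodule_size_cm:.1f} cm.")
        if s.followup_unoperated_negative:
            fu = s.followup_unoperated_negative
            extra.append(
                f"Follow-up of unoperated test-negatives (n={fu['n']}): "
                f"mean {fu['mean_days']:.0f} days, range {fu['min_days']}-{fu['max_days']}."
            )
        return "## Cohort characteristics\n\n" + table + "\n\n" + " ".join(extra)

    def _md_histology(self) -> str:
        if self.histology.empty:
            return "## Histology by subtype\n\nNo operated nodules with histology reports."
        rows = [
            [str(ix)] + [str(int(v)) for v in row] + [str(int(sum(row)))]
            for ix, row in zip(self.histology.index, self.histology.to_numpy())
        ]
        totals = self.histology.sum()
        rows.append(["**Total**"] + [str(int(v)) for v in totals] + [str(int(totals.sum()))])
        return "## Histology by subtype\n\n" + markdown_table(
            ["Subtype", "True negative", "False negative", "False positive",
             "True positive", "Total"],
            rows,
        )

    def _md_performance(self) -> str:
        a = self.adjusted
        header = ["Metric", "Naive (operated only)", "Adjusted (imputed negatives)"]
        rows = []
        for m in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "prevalence"):
            naive = getattr(self.performance_naive, m)
            adj = getattr(self.performance_adjusted, m)
            rows.append([
                m,
                f"{fmt_proportion_percent(naive)} [{naive.numerator}/{naive.denominator}]"
                if naive else "undefined",
                f"{fmt_proportion_percent(adj)} [{adj.numerator}/{adj.denominator}]"
                if adj else "undefined",
            ])
        cells = (
            f"Adjusted 2x2 - TP: {a.tp}, FP: {a.fp}, "
            f"FN: {a.fn_imputed} imputed + {a.fn_observed} observed ({a.fn_total}), "
            f"TN: {a.tn_imputed} imputed + {a.tn_observed} observed ({a.tn_total})."
        )
        caveat = (
            "Intervals on adjusted metrics apply the exact binomial method to "
            "imputed integer cells, which are not true binomial observations."
        )
        return "## Diagnostic performance\n\n" + markdown_table(header, rows) + \
            f"\n\n{cells}\n\n*{caveat}*"

    def _md_utility(self) -> str:
        u = self.utility
        rows = []
        for label, p in [
            ("Decisions supported, negative arm", u.support_when_negative),
            ("Decisions supported, positive arm", u.support_when_positive),
            ("Overall concordance", u.overall_concordance),
            ("Surgeries avoided", u.surgeries_avoided),
            ("Potentially unnecessary surgeries avoided", u.potentially_unnecessary_avoided),
        ]:
            rows.append([
                label,
                f"{fmt_proportion_percent(p)} [{p.numerator}/{p.denominator}]"
                if p else "undefined",
            ])
        assumptions = "\n".join(
            f"- {k}: {v}" for k, v in u.assumptions.items()
        )
        return ("## Clinical utility\n\n" + markdown_table(["Rate", "% (95% CI) [x/n]"], rows)
                + "\n\n### Assumptions\n\n" + assumptions)


def run_analysis(config: RunConfig, cohort: Optional[cm.CohortTable] = None) -> ReportBundle:
    """Run the full pipeline; pass ``cohort`` to skip file ingestion."""
    if cohort is None:
        try:
            cohort = cm.read_cohort(config.input_path)
        except (cm.SchemaError, cm.CohortValidationError, OSError) as exc:
            raise AnalysisError("ingest", str(exc)) from exc
    log.info("input records: %d", len(cohort))

    analysis, excl = cm.apply_exclusions(cohort)
    log.info("exclusions: %s; analyzable: %d", excl.n_excluded_by_reason, excl.n_analyzable)
    if len(analysis) == 0:
        raise AnalysisError("exclusions", "no analyzable nodules after exclusions")

    try:
        flow = cm.flow_counts(analysis)
        summary = cm.summarize(analysis, age_cut=config.age_cut, confidence=config.confidence)
        histology = cm.tabulate_histology(analysis)
    except ValueError as exc:
        raise AnalysisError("descriptives", str(exc)) from exc

    try:
        verified = perf.tally_verified(analysis)
        adjusted = perf.adjust_counts(verified, config.adjustment)
        log.info(
            "imputation: %d unoperated negatives -> %d benign + %d malignant (Se_ext=%g)",
            verified.n_negative_unoperated, adjusted.tn_imputed, adjusted.fn_imputed,
            config.adjustment.external_sensitivity,
        )
        p_naive = perf.compute_performance(verified, config.confidence)
        p_adj = perf.compute_performance(adjusted, config.confidence)
    except ValueError as exc:
        raise AnalysisError("performance", str(exc)) from exc

    try:
        utility = ut.utility_report(
            flow, adjusted, config.adjustment,
            confidence=config.confidence, counterfactual=config.counterfactual,
        )
    except ValueError as exc:
        raise AnalysisError("utility", str(exc)) from exc

    return ReportBundle(
        exclusion_log=excl,
        flow=flow,
        summary=summary,
        histology=histology,
        verified=verified,
        adjusted=adjusted,
        performance_naive=p_naive,
        performance_adjusted=p_adj,
        utility=utility,
        config=config,
    )
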