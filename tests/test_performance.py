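"""Verified tally, imputation of unverified negatives, performance metrics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thyverify.performance import (
    AdjustedCounts,
    AdjustmentConfig,
    PerformanceError,
    VerifiedCounts,
    adjust_counts,
    compute_performance,
    impute_unverified_negatives,
    tally_verified,
)
from thyverify.cohort import CohortTable, Histology, TestResult

from test_cohort import make_record


class TestTallyVerified:
    def test_replica_matches_study_counts(self, replica_verified):
        v = replica_verified
        assert (v.tp, v.fp, v.fn_operated, v.tn_operated) == (49, 29, 2, 5)
        assert v.n_negative_unoperated == 150
        assert v.n_positive_unoperated == 9
        assert v.n_positive_no_histology == 1

    def test_niftp_counted_as_true_positive(self, analysis_cohort):
        niftp = [
            r for r in analysis_cohort
            if r.histology is Histology.NIFTP and r.test_result is TestResult.POSITIVE
        ]
        assert len(niftp) == 2  # both inside the tp cell of the tally

    def test_no_surgeries_all_verified_cells_zero(self):
        v = tally_verified(CohortTable.from_records([make_record()]))
        assert (v.tp, v.fp, v.fn_operated, v.tn_operated) == (0, 0, 0, 0)
        assert v.n_negative_unoperated == 1

    def test_every_record_in_exactly_one_stratum(self, replica_verified):
        assert replica_verified.total == 245


class TestImputation:
    def test_study_split(self):
        cfg = AdjustmentConfig(external_sensitivity=0.946)
        assert impute_unverified_negatives(150, cfg) == (142, 8)

    def test_perfect_sensitivity_imputes_no_misses(self):
        cfg = AdjustmentConfig(external_sensitivity=1.0)
        assert impute_unverified_negatives(37, cfg) == (37, 0)

    def test_empty_stratum(self):
        assert impute_unverified_negatives(0, AdjustmentConfig()) == (0, 0)

    def test_symmetric_split(self):
        cfg = AdjustmentConfig(external_sensitivity=0.5)
        assert impute_unverified_negatives(100, cfg) == (50, 50)

    @pytest.mark.parametrize(
        "rounding,expected_fn", [("nearest", 8), ("floor", 8), ("ceiling", 9)]
    )
    def test_rounding_modes(self, rounding, expected_fn):
        cfg = AdjustmentConfig(external_sensitivity=0.946, rounding=rounding)
        tn, fn = impute_unverified_negatives(150, cfg)
        assert fn == expected_fn
        assert tn + fn == 150

    @given(
        n=st.integers(0, 500),
        se_lo=st.floats(0.5, 0.99),
        delta=st.floats(0.0, 0.01),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_imputed_misses_monotone_in_sensitivity(self, n, se_lo, delta):
        _, fn_lo = impute_unverified_negatives(n, AdjustmentConfig(external_sensitivity=se_lo))
        _, fn_hi = impute_unverified_negatives(
            n, AdjustmentConfig(external_sensitivity=min(se_lo + delta, 1.0))
        )
        assert fn_hi <= fn_lo


class TestAdjustCounts:
    def test_replica_adjusted_table(self, replica_adjusted):
        a = replica_adjusted
        assert a.to_dict() == {
            "tp": 49, "fp": 29, "fn_observed": 2, "fn_imputed": 8,
            "tn_observed": 5, "tn_imputed": 142, "fn_total": 10, "tn_total": 147,
        }

    def test_full_verification_copies_observed_cells(self):
        v = VerifiedCounts(tp=10, fp=3, fn_operated=2, tn_operated=20,
                           n_negative_unoperated=0, n_positive_unoperated=0)
        a = adjust_counts(v)
        assert (a.fn_imputed, a.tn_imputed) == (0, 0)
        assert (a.tp, a.fp, a.fn_observed, a.tn_observed) == (10, 3, 2, 20)

    def test_cohort_conservation(self, replica_verified, replica_adjusted):
        v, a = replica_verified, replica_adjusted
        assert (
            a.total + v.n_positive_unoperated + v.n_positive_no_histology == 245
        )


class TestComputePerformance:
    def test_adjusted_metrics_reproduce_study_ratios(self, replica_adjusted):
        rep = compute_performance(replica_adjusted)
        expected = {
            "sensitivity": (49, 59),
            "specificity": (147, 176),
            "ppv": (49, 78),
            "npv": (147, 157),
            "accuracy": (196, 235),
            "prevalence": (59, 235),
        }
        for metric, (x, n) in expected.items():
            prop = getattr(rep, metric)
            assert (prop.numerator, prop.denominator) == (x, n)

    def test_naive_mode_shows_verification_bias(self, replica_verified):
        rep = compute_performance(replica_verified)
        assert (rep.sensitivity.numerator, rep.sensitivity.denominator) == (49, 51)
        assert (rep.specificity.numerator, rep.specificity.denominator) == (5, 34)
        # operated-only specificity is wildly deflated vs the adjusted 83.5%
        assert rep.specificity.estimate < 0.2

    def test_adjusted_npv_at_least_naive_when_imputing_all_benign(self):
        v = VerifiedCounts(tp=5, fp=2, fn_operated=1, tn_operated=6,
                           n_negative_unoperated=40, n_positive_unoperated=0)
        naive = compute_performance(v)
        adjusted = compute_performance(
            adjust_counts(v, AdjustmentConfig(external_sensitivity=1.0))
        )
        assert adjusted.npv.estimate >= naive.npv.estimate

    def test_perfect_classifier(self):
        a = AdjustedCounts(tp=12, fp=0, fn_observed=0, fn_imputed=0,
                           tn_observed=0, tn_imputed=0)
        rep = compute_performance(a)
        assert rep.sensitivity.estimate == 1.0
        assert rep.ppv.estimate == 1.0
        assert rep.accuracy.estimate == 1.0
        assert rep.specificity is None  # no benign nodules: undefined, not 0

    def test_all_zero_table_is_error(self):
        v = VerifiedCounts(tp=0, fp=0, fn_operated=0, tn_operated=0,
                           n_negative_unoperated=3, n_positive_unoperated=0)
        with pytest.raises(PerformanceError, match="no verified outcomes"):
            compute_performance(v)
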