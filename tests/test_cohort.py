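"""Cohort model: ingestion, validation, exclusions, flow, descriptives."""

import io

import pytest

from thyverify.cohort import (
    Bethesda,
    CohortTable,
    CohortValidationError,
    ExclusionFlag,
    Histology,
    NoduleRecord,
    SchemaError,
    Sex,
    TestResult,
    Truth,
    apply_exclusions,
    flow_counts,
    read_cohort,
    summarize,
    tabulate_histology,
    truth_label,
    write_cohort,
)

HEADER = (
    "patient_id,nodule_id,age_years,sex,bethesda,nodule_size_cm,"
    "test_result,surgery,histology,histology_subtype,followup_days,exclusion_flag"
)


def make_record(**kw) -> NoduleRecord:
    base = dict(
        patient_id="P1",
        nodule_id="N1",
        age_years=50,
        sex=Sex.FEMALE,
        bethesda=Bethesda.IV,
        test_result=TestResult.NEGATIVE,
        surgery=False,
        histology=Histology.UNAVAILABLE,
    )
    base.update(kw)
    return NoduleRecord(**base)


class TestRecordInvariants:
    def test_histology_requires_surgery(self):
        with pytest.raises(ValueError, match="histology requires surgery"):
            make_record(surgery=False, histology=Histology.BENIGN)

    def test_minors_rejected(self):
        with pytest.raises(ValueError, match="age"):
            make_record(age_years=17)

    def test_negative_size_rejected(self):
        with pytest.raises(ValueError, match="size"):
            make_record(nodule_size_cm=-0.5)

    def test_truth_labels(self):
        assert truth_label(
            make_record(surgery=True, histology=Histology.NIFTP)
        ) is Truth.MALIGNANT
        assert truth_label(
            make_record(surgery=True, histology=Histology.BENIGN)
        ) is Truth.BENIGN
        assert truth_label(make_record(surgery=False)) is Truth.UNKNOWN


class TestReadCohort:
    def test_replica_fixture_has_256_records(self, replica):
        assert len(replica) == 256

    def test_empty_file_with_header(self):
        cohort = read_cohort(io.StringIO(HEADER + "\n"))
        assert len(cohort) == 0

    def test_missing_column_names_it(self):
        bad = HEADER.replace("test_result,", "")
        with pytest.raises(SchemaError, match="test_result"):
            read_cohort(io.StringIO(bad + "\n"))

    def test_invalid_row_reports_row_number(self):
        row = "P1,N1,50,female,IV,1.0,negative,false,benign,,," + "none"
        with pytest.raises(CohortValidationError, match="row 2"):
            read_cohort(io.StringIO(HEADER + "\n" + row + "\n"))

    def test_enums_case_insensitive(self):
        row = "P1,N1,50,Female,iv,1.0,NEGATIVE,False,Unavailable,,365,none"
        cohort = read_cohort(io.StringIO(HEADER + "\n" + row + "\n"))
        assert cohort.records[0].sex is Sex.FEMALE
        assert cohort.records[0].bethesda is Bethesda.IV

    def test_duplicate_nodule_id_rejected(self):
        row = "P1,N1,50,female,IV,1.0,negative,false,unavailable,,,none"
        with pytest.raises(SchemaError, match="duplicate"):
            read_cohort(io.StringIO(HEADER + "\n" + row + "\n" + row + "\n"))

    def test_unknown_column_warns_but_parses(self):
        row = "P1,N1,50,female,IV,1.0,negative,false,unavailable,,,none,x"
        with pytest.warns(UserWarning, match="unknown column"):
            cohort = read_cohort(io.StringIO(HEADER + ",extra\n" + row + "\n"))
        assert len(cohort) == 1

    def test_round_trip_identity(self, replica):
        buf = io.StringIO()
        write_cohort(replica, buf)
        buf.seek(0)
        again = read_cohort(buf)
        assert again.records == replica.records


class TestExclusions:
    def test_replica_exclusions(self, replica):
        cohort, log = apply_exclusions(replica)
        assert len(cohort) == 245
        assert log.to_dict() == {
            "n_input": 256,
            "n_excluded_by_reason": {"collision_tumor": 11},
            "n_analyzable": 245,
        }

    def test_no_flags_is_identity(self):
        cohort = CohortTable.from_records([make_record()])
        kept, log = apply_exclusions(cohort)
        assert kept.records == cohort.records
        assert log.n_excluded_by_reason == {}

    def test_all_flagged_yields_empty_cohort(self):
        cohort = CohortTable.from_records(
            [make_record(exclusion_flag=ExclusionFlag.UNMATCHED_NODULE)]
        )
        kept, log = apply_exclusions(cohort)
        assert len(kept) == 0
        assert log.n_analyzable == 0


class TestFlowCounts:
    def test_replica_flow_matches_study(self, replica_flow):
        assert replica_flow.to_dict() == {
            "n_analyzable": 245,
            "n_test_negative": 157,
            "n_test_positive": 88,
            "n_negative_operated": 7,
            "n_negative_unoperated": 150,
            "n_positive_operated": 79,
            "n_positive_unoperated": 9,
            "n_positive_operated_no_histology": 1,
        }

    def test_every_record_in_exactly_one_terminal_arm(self, replica_flow):
        f = replica_flow
        assert (
            f.n_negative_operated + f.n_negative_unoperated
            + f.n_positive_operated + f.n_positive_unoperated
            == f.n_analyzable
        )

    def test_degenerate_all_positive_operated(self):
        records = [
            make_record(
                nodule_id=f"N{i}", test_result=TestResult.POSITIVE,
                surgery=True, histology=Histology.MALIGNANT,
            )
            for i in range(4)
        ]
        f = flow_counts(CohortTable.from_records(records))
        assert f.n_positive_operated == 4
        assert f.n_test_negative == 0

    def test_refuses_unexcluded_cohort(self, replica):
        with pytest.raises(ValueError, match="apply_exclusions"):
            flow_counts(replica)


class TestSummarize:
    def test_stratified_counts_match_study_table(self, analysis_cohort):
        s = summarize(analysis_cohort)
        assert s.strata["age"] == {"20-54": (81, 58), ">54": (76, 30)}
        assert s.strata["sex"] == {"female": (127, 78), "male": (30, 10)}
        assert s.strata["bethesda"] == {"III": (35, 19), "IV": (122, 69)}
        assert s.strata["surgery"] == {"no": (150, 9), "yes": (7, 79)}

    def test_association_pvalues(self, analysis_cohort):
        s = summarize(analysis_cohort)
        assert round(s.pvalues["age"], 2) == 0.04
        assert s.pvalues["surgery"] < 0.001
        assert s.pvalues["bethesda"] > 0.9

    def test_followup_of_unoperated_negatives(self, analysis_cohort):
        fu = summarize(analysis_cohort).followup_unoperated_negative
        assert fu == {"n": 150, "mean_days": 706.0, "min_days": 10, "max_days": 1451}

    def test_percentages_sum_within_columns(self, analysis_cohort):
        s = summarize(analysis_cohort)
        for levels in s.strata.values():
            neg = sum(n for n, _ in levels.values())
            pos = sum(p for _, p in levels.values())
            assert neg == s.n_test_negative
            assert pos == s.n_test_positive

    def test_single_record_cohort(self):
        s = summarize(CohortTable.from_records([make_record(age_years=40)]))
        assert s.strata["age"]["20-54"] == (1, 0)
        assert s.strata["age"][">54"] == (0, 0)
        assert s.pvalues["age"] is None


class TestHistologyTable:
    def test_replica_matches_study_tally(self, analysis_cohort):
        table = tabulate_histology(analysis_cohort)
        assert table.loc["Follicular adenoma", "false_positive"] == 21
        assert table.loc["NIFTP", "true_positive"] == 2
        assert table.loc["Follicular adenoma", "true_negative"] == 4
        assert int(table.to_numpy().sum()) == 85

    def test_grand_total_reconciles_with_flow(self, analysis_cohort, replica_flow):
        table = tabulate_histology(analysis_cohort)
        f = replica_flow
        assert int(table.to_numpy().sum()) == (
            f.n_negative_operated + f.n_positive_operated
            - f.n_positive_operated_no_histology
        )

    def test_no_surgeries_gives_empty_table(self):
        table = tabulate_histology(CohortTable.from_records([make_record()]))
        assert table.empty

    def test_unknown_subtype_bucketed_as_other(self):
        rec = make_record(
            surgery=True, histology=Histology.BENIGN, histology_subtype="weird lesion"
        )
        with pytest.warns(UserWarning, match="controlled"):
            table = tabulate_histology(CohortTable.from_records([rec]))
        assert table.loc["other", "true_negative"] == 1
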