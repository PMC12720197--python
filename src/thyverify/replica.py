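"""Deterministic study-replica cohort.

Builds, record by record, a synthetic 256-nodule cohort whose every tallied
margin matches the published real-world validation cohort this package's
defaults emulate: 11 collision-tumor exclusions leaving 245 analyzable
nodules; 157 test-negative (150 unoperated, 5 true negative, 2 false
negative) and 88 test-positive (9 unoperated, 1 operated without a
retrievable histology report, 29 false positive, 49 true positive including
2 NIFTP); the exact histology-subtype distribution; per-arm age, sex and
Bethesda stratum counts; and follow-up for unoperated test-negatives with
mean 706 days on the range 10-1451.

The records themselves are synthetic (no individual-level data exist in
any public source); only the margins are exact.  Attributes are spread
across each arm with an even deterministic interleave so no covariate is
artifactually concentrated in one flow sub-block.  The same table ships as
``data/study_replica.csv`` for CLI use.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterator

from .cohort import (
    Bethesda,
    CohortTable,
    ExclusionFlag,
    Histology,
    NoduleRecord,
    Sex,
    TestResult,
    read_cohort,
)

__all__ = ["study_replica_cohort", "load_study_replica"]

# (subtype, histology, count) for each verified stratum
_TN_SUBTYPES = [
    ("Follicular adenoma", Histology.BENIGN, 4),
    ("Oncocytic adenoma of the thyroid", Histology.BENIGN, 1),
]
_FN_SUBTYPES = [
    ("Papillary thyroid micro/carcinoma variant follicular", Histology.MALIGNANT, 1),
    ("Follicular thyroid carcinoma minimally invasive", Histology.MALIGNANT, 1),
]
_FP_SUBTYPES = [
    ("Follicular adenoma", Histology.BENIGN, 21),
    ("Thyroid follicular nodular disease", Histology.BENIGN, 5),
    ("Oncocytic adenoma of the thyroid", Histology.BENIGN, 1),
    ("Thyroiditis", Histology.BENIGN, 2),
]
_TP_SUBTYPES = [
    ("Papillary thyroid micro/carcinoma variant follicular", Histology.MALIGNANT, 38),
    ("Follicular thyroid carcinoma minimally invasive", Histology.MALIGNANT, 4),
    ("Papillary thyroid micro/carcinoma classic", Histology.MALIGNANT, 2),
    ("Papillary thyroid micro/carcinoma subtype solid", Histology.MALIGNANT, 1),
    ("Papillary thyroid microcarcinoma subtype oncocytic", Histology.MALIGNANT, 1),
    ("Oncocytic microcarcinoma of the thyroid", Histology.MALIGNANT, 1),
    ("NIFTP", Histology.NIFTP, 2),
]

# per-arm stratum counts: (n_in_arm, n_age_young, n_female, n_bethesda_iv)
_NEG_STRATA = (157, 81, 127, 122)
_POS_STRATA = (88, 58, 78, 69)

_YOUNG_AGES = (28, 37, 45, 52)
_OLD_AGES = (56, 61, 66, 74)
_SIZES = (0.8, 1.0, 1.2, 1.4, 1.6)


def _spread(n_ones: int, n_total: int) -> list[bool]:
    """Exactly n_ones True values spread evenly over n_total positions."""
    return [
        (i + 1) * n_ones // n_total - i * n_ones // n_total == 1 for i in range(n_total)
    ]


def _arm_attributes(n: int, n_young: int, n_female: int, n_iv: int) -> Iterator[tuple]:
    young = _spread(n_young, n)
    female = _spread(n_female, n)
    beth_iv = _spread(n_iv, n)
    for i in range(n):
        age = _YOUNG_AGES[i % 4] if young[i] else _OLD_AGES[i % 4]
        yield (
            age,
            Sex.FEMALE if female[i] else Sex.MALE,
            Bethesda.IV if beth_iv[i] else Bethesda.III,
        )


def _followup_days() -> list[int]:
    # 150 values: mean exactly 706, min 10, max 1451
    days = [10, 1451, 657] + [706] * 147
    assert sum(days) == 150 * 706
    return days


def study_replica_cohort() -> CohortTable:
    """Build the 256-record replica cohort (deterministic, no RNG)."""
    records: list[NoduleRecord] = []
    neg_attrs = _arm_attributes(*_NEG_STRATA)
    pos_attrs = _arm_attributes(*_POS_STRATA)
    followups = iter(_followup_days())
    sizes = iter(_SIZES[i % 5] for i in range(245))
    nodule_no = 0
    patient_no = 0

    def new_ids() -> tuple[str, str]:
        nonlocal nodule_no, patient_no
        nodule_no += 1
        patient_no += 1
        return f"P{patient_no:03d}", f"N{nodule_no:03d}"

    def add(attrs, test, surgery, histology, subtype, followup=None, patient_id=None):
        nonlocal nodule_no
        age, sex, bethesda = next(attrs)
        pid, nid = new_ids()
        if patient_id is not None:
            pid = patient_id
        records.append(
            NoduleRecord(
                patient_id=pid,
                nodule_id=nid,
                age_years=age,
                sex=sex,
                bethesda=bethesda,
                test_result=test,
                surgery=surgery,
                histology=histology,
                histology_subtype=subtype,
                nodule_size_cm=next(sizes),
                followup_days=followup,
                exclusion_flag=ExclusionFlag.NONE,
            )
        )
        return records[-1]

    # negative arm: 150 unoperated, then 5 TN, then 2 FN
    for _ in range(150):
        add(neg_attrs, TestResult.NEGATIVE, False, Histology.UNAVAILABLE, None,
            followup=next(followups))
    for subtype, hist, count in _TN_SUBTYPES:
        for _ in range(count):
            add(neg_attrs, TestResult.NEGATIVE, True, hist, subtype)
    fn_records = []
    for subtype, hist, count in _FN_SUBTYPES:
        for _ in range(count):
            fn_records.append(add(neg_attrs, TestResult.NEGATIVE, True, hist, subtype))

    # positive arm: 49 TP (the first two share a patient with the two false
    # negatives — their surgeries were driven by the co-existing positive
    # nodule), 29 FP, 1 operated without histology, 9 unoperated
    tp_flat = [
        (subtype, hist) for subtype, hist, count in _TP_SUBTYPES for _ in range(count)
    ]
    for i, (subtype, hist) in enumerate(tp_flat):
        shared = fn_records[i].patient_id if i < len(fn_records) else None
        add(pos_attrs, TestResult.POSITIVE, True, hist, subtype, patient_id=shared)
        if shared is not None:
            patient_no -= 1  # id was reused, counter should not advance
    for subtype, hist, count in _FP_SUBTYPES:
        for _ in range(count):
            add(pos_attrs, TestResult.POSITIVE, True, hist, subtype)
    add(pos_attrs, TestResult.POSITIVE, True, Histology.UNAVAILABLE, None)
    shared_unop = None
    for i in range(9):
        # three unoperated positives share patients with unoperated negatives
        # so the replica has 251 distinct patients for 256 nodules
        pid = records[i].patient_id if i < 3 else None
        add(pos_attrs, TestResult.POSITIVE, False, Histology.UNAVAILABLE, None, patient_id=pid)
        if pid is not None:
            patient_no -= 1

    # 11 collision-tumor exclusions (2 positive, 9 negative): never analyzed
    excl_attrs = _arm_attributes(11, 6, 9, 8)
    for i in range(11):
        age, sex, bethesda = next(excl_attrs)
        pid, nid = new_ids()
        records.append(
            NoduleRecord(
                patient_id=pid,
                nodule_id=nid,
                age_years=age,
                sex=sex,
                bethesda=bethesda,
                test_result=TestResult.POSITIVE if i < 2 else TestResult.NEGATIVE,
                surgery=True,
                histology=Histology.MALIGNANT,
                histology_subtype=None,
                nodule_size_cm=1.2,
                followup_days=None,
                exclusion_flag=ExclusionFlag.COLLISION_TUMOR,
            )
        )
    return CohortTable.from_records(records, provenance="study_replica")


def load_study_replica() -> CohortTable:
    """Load the shipped ``data/study_replica.csv`` (identical to the builder)."""
    ref = resources.files("thyverify").joinpath("data/study_replica.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return read_cohort(fh, provenance="study_replica")
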