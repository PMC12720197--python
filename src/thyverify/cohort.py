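"""Cohort data model, CSV ingestion, exclusion rules and descriptives.

A cohort is one row per *tested nodule* (never per patient: multi-nodule
patients contribute one record per nodule, each judged on its own cytology,
test result and histology).  Surgical histopathology is the reference
standard, so truth is observed only for operated nodules; non-invasive
follicular thyroid neoplasms with papillary-like nuclear features (NIFTP)
count as malignant because their diagnosis itself requires resection.
"""

from __future__ import annotations

import io
import warnings
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .exact import ContingencyTable, association_pvalue

__all__ = [
    "Sex",
    "Bethesda",
    "TestResult",
    "Histology",
    "ExclusionFlag",
    "Truth",
    "NoduleRecord",
    "CohortTable",
    "ExclusionLog",
    "CohortSummary",
    "FlowCounts",
    "SchemaError",
    "CohortValidationError",
    "HISTOLOGY_SUBTYPES",
    "read_cohort",
    "write_cohort",
    "apply_exclusions",
    "truth_label",
    "flow_counts",
    "summarize",
    "tabulate_histology",
]


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class Bethesda(str, Enum):
    III = "III"
    IV = "IV"


class TestResult(str, Enum):
    NEGATIVE = "negative"
    POSITIVE = "positive"


class Histology(str, Enum):
    BENIGN = "benign"
    MALIGNANT = "malignant"
    NIFTP = "NIFTP"
    UNAVAILABLE = "unavailable"


class ExclusionFlag(str, Enum):
    NONE = "none"
    COLLISION_TUMOR = "collision_tumor"
    UNMATCHED_NODULE = "unmatched_nodule"


class Truth(str, Enum):
    MALIGNANT = "malignant"
    BENIGN = "benign"
    UNKNOWN = "unknown"


#: Controlled vocabulary for ``histology_subtype`` (case-insensitive after
#: whitespace normalisation); anything else is bucketed as "other".
HISTOLOGY_SUBTYPES: tuple[str, ...] = (
    "Follicular adenoma",
    "Oncocytic adenoma of the thyroid",
    "Thyroid follicular nodular disease",
    "Thyroiditis",
    "Papillary thyroid micro/carcinoma variant follicular",
    "Papillary thyroid micro/carcinoma classic",
    "Papillary thyroid micro/carcinoma subtype solid",
    "Papillary thyroid microcarcinoma subtype oncocytic",
    "Oncocytic microcarcinoma of the thyroid",
    "Follicular thyroid carcinoma minimally invasive",
    "NIFTP",
)

_SUBTYPE_LOOKUP = {" ".join(s.split()).lower(): s for s in HISTOLOGY_SUBTYPES}


class SchemaError(ValueError):
    """The CSV is structurally unusable (missing column, duplicate ids)."""


class CohortValidationError(ValueError):
    """One or more rows violate the record invariants; carries all of them."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass(frozen=True)
class NoduleRecord:
    """One tested nodule.

    Invariants enforced at construction: adults only (age >= 18), histology
    exists only for operated nodules, NIFTP implies surgery, positive size.
    """

    patient_id: str
    nodule_id: str
    age_years: int
    sex: Sex
    bethesda: Bethesda
    test_result: TestResult
    surgery: bool
    histology: Histology = Histology.UNAVAILABLE
    histology_subtype: Optional[str] = None
    nodule_size_cm: Optional[float] = None
    followup_days: Optional[int] = None
    exclusion_flag: ExclusionFlag = ExclusionFlag.NONE

    def __post_init__(self) -> None:
        if self.age_years < 18:
            raise ValueError(f"age_years must be >= 18, got {self.age_years}")
        if not self.surgery and self.histology is not Histology.UNAVAILABLE:
            raise ValueError(
                f"nodule {self.nodule_id}: histology requires surgery "
                f"(surgery=false but histology={self.histology.value})"
            )
        if self.histology is Histology.NIFTP and not self.surgery:
            raise ValueError(f"nodule {self.nodule_id}: NIFTP diagnosis requires surgery")
        if self.nodule_size_cm is not None and not self.nodule_size_cm > 0:
            raise ValueError(f"nodule {self.nodule_id}: nodule_size_cm must be positive")
        if self.followup_days is not None and self.followup_days < 0:
            raise ValueError(f"nodule {self.nodule_id}: followup_days must be >= 0")


@dataclass(frozen=True)
class CohortTable:
    """An ordered, id-unique collection of nodule records."""

    records: tuple[NoduleRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.nodule_id for r in self.records]
        dupes = [k for k, v in Counter(ids).items() if v > 1]
        if dupes:
            raise SchemaError(f"duplicate nodule_id values: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @classmethod
    def from_records(cls, records: Iterable[NoduleRecord], provenance: str = "") -> "CohortTable":
        return cls(records=tuple(records), provenance=provenance)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "nodule_id": r.nodule_id,
                    "age_years": r.age_years,
                    "sex": r.sex.value,
                    "bethesda": r.bethesda.value,
                    "nodule_size_cm": r.nodule_size_cm,
                    "test_result": r.test_result.value,
                    "surgery": r.surgery,
                    "histology": r.histology.value,
                    "histology_subtype": r.histology_subtype,
                    "followup_days": r.followup_days,
                    "exclusion_flag": r.exclusion_flag.value,
                }
            )
        return pd.DataFrame(rows, columns=_COLUMNS)


@dataclass(frozen=True)
class ExclusionLog:
    """Reconciliation of input vs analyzable record counts."""

    n_input: int
    n_excluded_by_reason: dict
    n_analyzable: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_analyzable + sum(self.n_excluded_by_reason.values()):
            raise ValueError("exclusion log does not reconcile input and output sizes")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_by_reason": dict(self.n_excluded_by_reason),
            "n_analyzable": self.n_analyzable,
        }


@dataclass(frozen=True)
class FlowCounts:
    """Arm counts of the study flow: test result x surgery x histology availability."""

    n_analyzable: int
    n_test_negative: int
    n_test_positive: int
    n_negative_operated: int
    n_negative_unoperated: int
    n_positive_operated: int
    n_positive_unoperated: int
    n_positive_operated_no_histology: int

    def __post_init__(self) -> None:
        if self.n_analyzable != self.n_test_negative + self.n_test_positive:
            raise ValueError("flow counts: arms do not sum to cohort size")
        if self.n_test_negative != self.n_negative_operated + self.n_negative_unoperated:
            raise ValueError("flow counts: negative arm does not reconcile")
        if self.n_test_positive != self.n_positive_operated + self.n_positive_unoperated:
            raise ValueError("flow counts: positive arm does not reconcile")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive cohort summary stratified by test result.

    ``strata`` maps a stratifier name to an ordered dict of
    ``level -> (n_test_negative, n_test_positive)``; ``pvalues`` carries the
    association p-value per stratifier and ``tests`` the test that produced
    it (continuity-corrected chi-square by default, Fisher's exact when any
    expected cell is below 5).
    """

    n_analyzable: int
    n_test_negative: int
    n_test_positive: int
    strata: dict
    pvalues: dict
    tests: dict
    mean_age_years: float
    mean_nodule_size_cm: Optional[float]
    followup_unoperated_negative: Optional[dict]
    age_cut: int = 54

    def to_dict(self) -> dict:
        return {
            "n_analyzable": self.n_analyzable,
            "n_test_negative": self.n_test_negative,
            "n_test_positive": self.n_test_positive,
            "strata": {k: {lvl: list(v) for lvl, v in d.items()} for k, d in self.strata.items()},
            "pvalues": dict(self.pvalues),
            "tests": dict(self.tests),
            "mean_age_years": self.mean_age_years,
            "mean_nodule_size_cm": self.mean_nodule_size_cm,
            "followup_unoperated_negative": self.followup_unoperated_negative,
            "age_cut": self.age_cut,
        }


_COLUMNS = [
    "patient_id",
    "nodule_id",
    "age_years",
    "sex",
    "bethesda",
    "nodule_size_cm",
    "test_result",
    "surgery",
    "histology",
    "histology_subtype",
    "followup_days",
    "exclusion_flag",
]

_OPTIONAL_COLUMNS = {"nodule_size_cm", "histology_subtype", "followup_days"}
_REQUIRED_COLUMNS = [c for c in _COLUMNS if c not in _OPTIONAL_COLUMNS]

_BOOL_VALUES = {
    "true": True, "false": False, "yes": True, "no": False, "1": True, "0": False,
}


def _parse_enum(enum_cls, raw: str, column: str):
    lookup = {m.value.lower(): m for m in enum_cls}
    key = raw.strip().lower()
    if key not in lookup:
        allowed = ", ".join(m.value for m in enum_cls)
        raise ValueError(f"invalid {column} value {raw!r} (allowed: {allowed})")
    return lookup[key]


def read_cohort(source: Union[str, "io.TextIOBase"], provenance: str = "") -> CohortTable:
    """Read and validate a cohort CSV (path or open text stream).

    Every row is either parsed into a :class:`NoduleRecord` or reported in a
    single :class:`CohortValidationError` naming its row number.  Unknown
    columns are ignored with a warning; a missing required column raises
    :class:`SchemaError` immediately.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in _COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown column(s): {', '.join(unknown)}", stacklevel=2)

    records: list[NoduleRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # CSV line numbers
        row = row._asdict()
        try:
            records.append(_parse_row(row))
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise CohortValidationError(errors)
    if not provenance and isinstance(source, str):
        provenance = source
    return CohortTable.from_records(records, provenance=provenance)


def _parse_row(row: dict) -> NoduleRecord:
    def opt(column):
        return row.get(column, "").strip() or None

    surgery_raw = row["surgery"].strip().lower()
    if surgery_raw not in _BOOL_VALUES:
        raise ValueError(f"invalid surgery value {row['surgery']!r}")
    size = opt("nodule_size_cm")
    followup = opt("followup_days")
    return NoduleRecord(
        patient_id=row["patient_id"].strip(),
        nodule_id=row["nodule_id"].strip(),
        age_years=int(row["age_years"]),
        sex=_parse_enum(Sex, row["sex"], "sex"),
        bethesda=_parse_enum(Bethesda, row["bethesda"], "bethesda"),
        test_result=_parse_enum(TestResult, row["test_result"], "test_result"),
        surgery=_BOOL_VALUES[surgery_raw],
        histology=_parse_enum(Histology, row["histology"], "histology"),
        histology_subtype=opt("histology_subtype"),
        nodule_size_cm=float(size) if size is not None else None,
        followup_days=int(followup) if followup is not None else None,
        exclusion_flag=_parse_enum(ExclusionFlag, row["exclusion_flag"], "exclusion_flag"),
    )


def write_cohort(cohort: CohortTable, path_or_buffer) -> None:
    """Write a cohort CSV that :func:`read_cohort` round-trips exactly."""
    df = cohort.to_dataframe()
    df["followup_days"] = df["followup_days"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df["nodule_size_cm"] = df["nodule_size_cm"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df["surgery"] = df["surgery"].map({True: "true", False: "false"})
    df = df.fillna("")
    df.to_csv(path_or_buffer, index=False)


def apply_exclusions(cohort: CohortTable) -> tuple[CohortTable, ExclusionLog]:
    """Drop flagged records (collision tumors, unmatched nodules) and log counts."""
    kept = [r for r in cohort if r.exclusion_flag is ExclusionFlag.NONE]
    reasons = Counter(
        r.exclusion_flag.value for r in cohort if r.exclusion_flag is not ExclusionFlag.NONE
    )
    log = ExclusionLog(
        n_input=len(cohort),
        n_excluded_by_reason=dict(reasons),
        n_analyzable=len(kept),
    )
    return CohortTable.from_records(kept, provenance=cohort.provenance), log


def truth_label(record: NoduleRecord) -> Truth:
    """Reference-standard label: histology with NIFTP counted as malignant."""
    if record.histology in (Histology.MALIGNANT, Histology.NIFTP):
        return Truth.MALIGNANT
    if record.histology is Histology.BENIGN:
        return Truth.BENIGN
    return Truth.UNKNOWN


def _check_analysis_cohort(cohort: CohortTable) -> None:
    if any(r.exclusion_flag is not ExclusionFlag.NONE for r in cohort):
        raise ValueError("cohort still contains excluded records; run apply_exclusions first")


def flow_counts(cohort: CohortTable) -> FlowCounts:
    """Tally the study-flow arms of a post-exclusion cohort."""
    _check_analysis_cohort(cohort)
    neg = [r for r in cohort if r.test_result is TestResult.NEGATIVE]
    pos = [r for r in cohort if r.test_result is TestResult.POSITIVE]
    pos_op = [r for r in pos if r.surgery]
    return FlowCounts(
        n_analyzable=len(cohort),
        n_test_negative=len(neg),
        n_test_positive=len(pos),
        n_negative_operated=sum(r.surgery for r in neg),
        n_negative_unoperated=sum(not r.surgery for r in neg),
        n_positive_operated=len(pos_op),
        n_positive_unoperated=sum(not r.surgery for r in pos),
        n_positive_operated_no_histology=sum(
            r.histology is Histology.UNAVAILABLE for r in pos_op
        ),
    )


def summarize(cohort: CohortTable, age_cut: int = 54, confidence: float = 0.95) -> CohortSummary:
    """Descriptive summary stratified by test result (age, sex, Bethesda, surgery).

    Age is dichotomised at ``age_cut`` (default 54: 20-54 vs >54).  Each
    stratifier gets an association p-value against the test result via
    :func:`thyverify.exact.association_pvalue`; strata with a zero margin
    report no p-value.
    """
    _check_analysis_cohort(cohort)
    neg = [r for r in cohort if r.test_result is TestResult.NEGATIVE]
    pos = [r for r in cohort if r.test_result is TestResult.POSITIVE]

    def stratify(name: str, levels: list[str], key) -> dict:
        return {
            name: {
                lvl: (sum(key(r) == lvl for r in neg), sum(key(r) == lvl for r in pos))
                for lvl in levels
            }
        }

    strata: dict = {}
    strata.update(
        stratify("age", [f"20-{age_cut}", f">{age_cut}"],
                 lambda r: f"20-{age_cut}" if r.age_years <= age_cut else f">{age_cut}")
    )
    strata.update(stratify("sex", ["female", "male"], lambda r: r.sex.value))
    strata.update(stratify("bethesda", ["III", "IV"], lambda r: r.bethesda.value))
    strata.update(stratify("surgery", ["no", "yes"], lambda r: "yes" if r.surgery else "no"))

    pvalues: dict = {}
    tests: dict = {}
    for name, levels in strata.items():
        cells = [[n, p] for (n, p) in levels.values()]
        row_ok = all(sum(row) > 0 for row in cells)
        col_ok = all(sum(col) > 0 for col in zip(*cells))
        if not (row_ok and col_ok):
            pvalues[name], tests[name] = None, "not_applicable"
            continue
        try:
            table = ContingencyTable.from_array(cells)
            pvalues[name], tests[name] = association_pvalue(table)
        except ValueError:
            pvalues[name], tests[name] = None, "not_applicable"

    sizes = [r.nodule_size_cm for r in cohort if r.nodule_size_cm is not None]
    fu = [
        r.followup_days
        for r in neg
        if not r.surgery and r.followup_days is not None
    ]
    followup = None
    if fu:
        followup = {
            "n": len(fu),
            "mean_days": float(np.mean(fu)),
            "min_days": int(min(fu)),
            "max_days": int(max(fu)),
        }
    return CohortSummary(
        n_analyzable=len(cohort),
        n_test_negative=len(neg),
        n_test_positive=len(pos),
        strata=strata,
        pvalues=pvalues,
        tests=tests,
        mean_age_years=float(np.mean([r.age_years for r in cohort])) if len(cohort) else float("nan"),
        mean_nodule_size_cm=float(np.mean(sizes)) if sizes else None,
        followup_unoperated_negative=followup,
        age_cut=age_cut,
    )


def tabulate_histology(cohort: CohortTable) -> pd.DataFrame:
    """Histology-subtype tally among operated nodules with available reports.

    Returns a DataFrame indexed by subtype with integer columns
    ``true_negative``, ``false_negative``, ``false_positive`` and
    ``true_positive`` (test result crossed with the malignant/benign truth
    label).  Subtype strings outside the controlled vocabulary are bucketed
    as ``"other"`` with a warning; operated records with no subtype string
    are bucketed as ``"unspecified"``.  The grand total equals the number
    of operated nodules with an available histology report.
    """
    _check_analysis_cohort(cohort)
    cols = ["true_negative", "false_negative", "false_positive", "true_positive"]
    counts: dict[str, Counter] = {}
    for r in cohort:
        if not r.surgery or r.histology is Histology.UNAVAILABLE:
            continue
        truth = truth_label(r)
        if r.test_result is TestResult.NEGATIVE:
            col = "false_negative" if truth is Truth.MALIGNANT else "true_negative"
        else:
            col = "true_positive" if truth is Truth.MALIGNANT else "false_positive"
        if r.histology_subtype is None:
            subtype = "unspecified"
        else:
            key = " ".join(r.histology_subtype.split()).lower()
            subtype = _SUBTYPE_LOOKUP.get(key)
            if subtype is None:
                warnings.warn(
                    f"histology_subtype {r.histology_subtype!r} outside the controlled "
                    "vocabulary; bucketed as 'other'",
                    stacklevel=2,
                )
                subtype = "other"
        counts.setdefault(subtype, Counter())[col] += 1

    order = [s for s in HISTOLOGY_SUBTYPES if s in counts]
    order += [s for s in ("other", "unspecified") if s in counts]
    data = {c: [counts[s].get(c, 0) for s in order] for c in cols}
    return pd.DataFrame(data, index=pd.Index(order, name="histology_subtype"), dtype=int)
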