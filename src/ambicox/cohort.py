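"""Ambispective cohort data model.

One row per patient, all times expressed in years since the first venous
thrombosis (VT).  Patients fall into four configurations:

* Case 1 -- single VT before inclusion, responded at recontact, no
  recurrence observed during follow-up.
* Case 2 -- single VT before inclusion, responded, recurrence observed
  between inclusion and the recontact collection time.
* Case 3 -- single VT before inclusion, lost to follow-up at recontact
  (no post-inclusion recurrence information).
* Case 4 -- both the first VT and the recurrence occurred before inclusion.

The *prospective* analysis uses only the post-inclusion experience of
Cases 1-2 (delayed entry at inclusion); the *ambispective* analysis starts
every at-risk period at the first VT and also uses the pre-inclusion
recurrences of Case 4 and the pre-inclusion survival of Case 3.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ABO_NON_REFERENCE = ("A1", "A2", "B", "O2")

VITAL_STATES = ("alive", "dead", "unknown")

PROSPECTIVE = "prospective"
AMBISPECTIVE = "ambispective"
DESIGNS = (PROSPECTIVE, AMBISPECTIVE)


class CaseLabel(enum.Enum):
    CASE1 = 1
    CASE2 = 2
    CASE3 = 3
    CASE4 = 4


@dataclass
class SubjectRecord:
    """One patient's timeline and covariates.

    ``abo_dosages`` carries the additive diplotype coding: counts of the
    A1, A2, B and O2 haplotypes (the O1 reference count is implicit,
    2 minus their sum); ``None`` when genotypes are absent or unresolved.
    """

    subject_id: str
    sex: int  # 1 = male
    age_first_vt: float  # years
    provoked_first_vt: int
    dvt_first_vt: int  # 1 = DVT, 0 = PE
    pcs: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    abo_dosages: dict[str, int] | None = None
    t_inclusion: float = 0.0
    recurrence_observed: int = 0
    t_recurrence: float | None = None
    t_collection: float = 0.0
    responded_recontact: int = 0
    vital_status: str = "unknown"
    t_last_vital: float | None = None

    def replace(self, **changes) -> "SubjectRecord":
        return replace(self, **changes)


@dataclass(frozen=True)
class RiskInterval:
    """Half-open at-risk period ``(entry, exit]`` with an event flag."""

    entry: float
    exit: float
    event: int
    weight: float = 1.0

    def __post_init__(self):
        if not self.entry < self.exit:
            raise ValueError(
                f"timeline inconsistency: interval ({self.entry}, {self.exit}] is empty"
            )
        if not self.weight > 0:
            raise ValueError("interval weight must be positive")


@dataclass
class ValidationReport:
    """Outcome of cohort validation: accepted records plus, for every
    rejected row, the subject id and a reason code.  Nothing is silently
    dropped."""

    valid: list[SubjectRecord]
    rejected: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rejected, columns=["subject_id", "reason"])


def _record_issues(r: SubjectRecord) -> list[str]:
    issues = []
    if r.sex not in (0, 1):
        issues.append("sex must be 0/1")
    if r.provoked_first_vt not in (0, 1):
        issues.append("provoked_first_vt must be 0/1")
    if r.dvt_first_vt not in (0, 1):
        issues.append("dvt_first_vt must be 0/1")
    if len(r.pcs) != 4 or not all(np.isfinite(p) for p in r.pcs):
        issues.append("pcs must be 4 finite values")
    if not (np.isfinite(r.age_first_vt) and r.age_first_vt >= 0):
        issues.append("age_first_vt must be non-negative")
    for name in ("t_inclusion", "t_collection"):
        v = getattr(r, name)
        if v is None or not np.isfinite(v) or v < 0:
            issues.append(f"{name} must be a non-negative time offset")
            return issues
    if r.recurrence_observed not in (0, 1):
        issues.append("recurrence_observed must be 0/1")
    if r.responded_recontact not in (0, 1):
        issues.append("responded_recontact must be 0/1")
    if r.vital_status not in VITAL_STATES:
        issues.append("vital_status must be alive/dead/unknown")
    if r.recurrence_observed and r.t_recurrence is None:
        issues.append("recurrence_observed without t_recurrence")
    if not r.recurrence_observed and r.t_recurrence is not None:
        issues.append("t_recurrence present without recurrence_observed")
    if r.t_recurrence is not None:
        if not np.isfinite(r.t_recurrence) or r.t_recurrence < 0:
            issues.append("t_recurrence must be a non-negative time offset")
        elif r.t_recurrence > r.t_collection:
            issues.append("t_recurrence > t_collection")
    if r.t_inclusion > r.t_collection:
        issues.append("t_inclusion > t_collection")
    if r.vital_status != "unknown":
        if r.t_last_vital is None or not np.isfinite(r.t_last_vital):
            issues.append("known vital_status requires t_last_vital")
        elif r.t_last_vital < r.t_inclusion:
            issues.append("t_last_vital < t_inclusion")
    # a recurrence known for a non-responder can only have been recorded at
    # inclusion, i.e. it must be pre-inclusion; anything else is inconsistent
    if (
        r.recurrence_observed
        and not r.responded_recontact
        and r.t_recurrence is not None
        and r.t_recurrence >= r.t_inclusion
    ):
        issues.append("post-inclusion recurrence without recontact response")
    return issues


def validate_cohort(records: Iterable[SubjectRecord]) -> ValidationReport:
    """Check every record against the timeline invariants.

    Raises on an empty collection or duplicated subject ids; individual
    inconsistent rows are rejected with a reason, never silently dropped.
    """
    records = list(records)
    if not records:
        raise ValueError("empty cohort")
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicated subject_id: {dupes}")
    report = ValidationReport(valid=[])
    for r in records:
        issues = _record_issues(r)
        if issues:
            report.rejected.append((r.subject_id, "; ".join(issues)))
        else:
            report.valid.append(r)
    if report.rejected:
        logger.info("validation rejected %d of %d records", report.n_rejected, len(records))
    return report


def classify_case(record: SubjectRecord) -> CaseLabel:
    """Assign the patient to one of the four design configurations.

    A recurrence exactly at the inclusion time counts as post-inclusion
    (Case 2): that is when it would have been recorded prospectively.
    """
    if record.recurrence_observed:
        if record.t_recurrence is None:
            raise ValueError(
                f"subject {record.subject_id}: recurrence_observed without t_recurrence"
            )
        if record.t_recurrence < record.t_inclusion:
            return CaseLabel.CASE4
    if not record.responded_recontact:
        return CaseLabel.CASE3
    if record.recurrence_observed:
        return CaseLabel.CASE2
    return CaseLabel.CASE1


def make_intervals(record: SubjectRecord, design: str) -> RiskInterval | None:
    """At-risk interval for one patient under the given design.

    Ambispective: entry at the first VT (time 0); exit at the recurrence
    (event) for Cases 2/4, at the collection time for Case 1, at inclusion
    for Case 3.  Prospective: delayed entry at inclusion, only Cases 1-2
    contribute; Cases 3-4 return ``None``.
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}")
    case = classify_case(record)
    if design == AMBISPECTIVE:
        if case in (CaseLabel.CASE2, CaseLabel.CASE4):
            return RiskInterval(0.0, float(record.t_recurrence), 1)
        if case is CaseLabel.CASE1:
            return RiskInterval(0.0, float(record.t_collection), 0)
        return RiskInterval(0.0, float(record.t_inclusion), 0)
    if case is CaseLabel.CASE1:
        return RiskInterval(float(record.t_inclusion), float(record.t_collection), 0)
    if case is CaseLabel.CASE2:
        return RiskInterval(float(record.t_inclusion), float(record.t_recurrence), 1)
    return None


# ---------------------------------------------------------------------------
# CSV input/output

_CSV_COLUMNS = [
    "subject_id",
    "sex",
    "age_first_vt",
    "provoked_first_vt",
    "dvt_first_vt",
    "pc1",
    "pc2",
    "pc3",
    "pc4",
    "abo_A1",
    "abo_A2",
    "abo_B",
    "abo_O2",
    "t_inclusion",
    "recurrence_observed",
    "t_recurrence",
    "t_collection",
    "responded_recontact",
    "vital_status",
    "t_last_vital",
]


def read_cohort(path) -> list[SubjectRecord]:
    """Read a cohort CSV (one header row, '#' comment lines permitted,
    missing values as empty cells)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns and not c.startswith("abo_")]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")
    has_abo = all(f"abo_{h}" in df.columns for h in ABO_NON_REFERENCE)
    records = []
    for row in df.itertuples(index=False):
        abo = None
        if has_abo:
            vals = [getattr(row, f"abo_{h}") for h in ABO_NON_REFERENCE]
            if not any(pd.isna(v) for v in vals):
                abo = {h: int(v) for h, v in zip(ABO_NON_REFERENCE, vals)}
        vital = row.vital_status
        vital = "unknown" if pd.isna(vital) else str(vital)
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                sex=int(row.sex),
                age_first_vt=float(row.age_first_vt),
                provoked_first_vt=int(row.provoked_first_vt),
                dvt_first_vt=int(row.dvt_first_vt),
                pcs=tuple(float(getattr(row, f"pc{i}")) for i in range(1, 5)),
                abo_dosages=abo,
                t_inclusion=float(row.t_inclusion),
                recurrence_observed=int(row.recurrence_observed),
                t_recurrence=None if pd.isna(row.t_recurrence) else float(row.t_recurrence),
                t_collection=float(row.t_collection),
                responded_recontact=int(row.responded_recontact),
                vital_status=vital,
                t_last_vital=None if pd.isna(row.t_last_vital) else float(row.t_last_vital),
            )
        )
    return records


def cohort_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "sex": r.sex,
            "age_first_vt": r.age_first_vt,
            "provoked_first_vt": r.provoked_first_vt,
            "dvt_first_vt": r.dvt_first_vt,
            **{f"pc{i + 1}": v for i, v in enumerate(r.pcs)},
            **{
                f"abo_{h}": (np.nan if r.abo_dosages is None else r.abo_dosages[h])
                for h in ABO_NON_REFERENCE
            },
            "t_inclusion": r.t_inclusion,
            "recurrence_observed": r.recurrence_observed,
            "t_recurrence": np.nan if r.t_recurrence is None else r.t_recurrence,
            "t_collection": r.t_collection,
            "responded_recontact": r.responded_recontact,
            "vital_status": r.vital_status,
            "t_last_vital": np.nan if r.t_last_vital is None else r.t_last_vital,
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_cohort(records: Sequence[SubjectRecord], path) -> None:
    cohort_frame(records).to_csv(path, index=False)
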