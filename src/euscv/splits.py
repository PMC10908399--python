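"""Factor-based patient grouping and role allotments.

The cross-validation framework divides *patients* (never images) into k=5
groups, so that no patient's images can appear in more than one of the
training / validation / test roles — the grouped-split guarantee against
information leakage.  Patients are first totally ordered by one of five
clinical factors:

* CHR — chronology of the EUS sessions (session date),
* AGE — age in years,
* BMI — body-mass index,
* SAI — self-reported alcohol intake (g ethanol/day),
* EDA — endoscopists' diagnostic accuracy (fraction of raters correct),

and then divided in one of two manners:

* *ordered*: contiguous blocks of the ranked list, concentrating similar
  factor values within groups;
* *balanced*: stride (round-robin) assignment, spreading factor values
  evenly across groups.

For k groups there are k*(k-1) role allotments (ordered pairs of test and
validation groups; the remaining k-2 groups train), i.e. 20 for k=5: each
test group is scored by an ensemble of the 4 validation-rotation models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .cohort import PatientRecord

__all__ = [
    "FACTORS",
    "factor_key",
    "GroupDivision",
    "RoleAllotment",
    "LeakageReport",
    "order_patients",
    "divide",
    "enumerate_allotments",
    "check_leakage",
    "write_division",
    "read_division",
]

#: The five split factors and their key functions on a patient record.
FACTORS: dict[str, Callable[[PatientRecord], float]] = {
    "CHR": lambda p: p.session_date,
    "AGE": lambda p: p.age_years,
    "BMI": lambda p: p.bmi,
    "SAI": lambda p: p.alcohol_g_per_day,
    "EDA": lambda p: p.eda_score,
}


def factor_key(factor: str) -> Callable[[PatientRecord], float]:
    try:
        return FACTORS[factor.upper()]
    except KeyError:
        raise KeyError(f"unknown factor {factor!r}; expected one of {sorted(FACTORS)}") from None


@dataclass(frozen=True)
class GroupDivision:
    """Assignment of every patient to exactly one of k groups."""

    factor: str
    mode: str  # "ordered" | "balanced"
    k: int
    assignment: Mapping[str, int]  # patient_id -> group index 0..k-1

    def group_members(self, group: int) -> list[str]:
        return sorted(pid for pid, g in self.assignment.items() if g == group)

    def group_sizes(self) -> list[int]:
        return [len(self.group_members(g)) for g in range(self.k)]


@dataclass(frozen=True)
class RoleAllotment:
    """One (test, validation, training) role pattern over the k groups."""

    test_group: int
    validation_group: int
    training_groups: tuple[int, ...]

    def __post_init__(self):
        roles = {self.test_group, self.validation_group, *self.training_groups}
        k = 2 + len(self.training_groups)
        if self.test_group == self.validation_group or roles != set(range(k)):
            raise ValueError(f"roles must partition the groups: {self}")


@dataclass(frozen=True)
class LeakageReport:
    """Outcome of a patient-level leakage audit."""

    passed: bool
    offending: dict[str, list[str]]  # patient_id -> roles it contributed to

    def __bool__(self) -> bool:
        return self.passed


def order_patients(cohort: Sequence[PatientRecord], factor: str) -> list[str]:
    """Rank patient ids ascending by the factor key; ties broken by
    patient_id (lexicographic), giving a deterministic total order."""
    key = factor_key(factor)
    decorated = []
    for p in cohort:
        value = key(p)
        if value is None:
            raise ValueError(f"patient {p.patient_id} has no value for factor {factor}")
        decorated.append((float(value), p.patient_id))
    decorated.sort()
    return [pid for _, pid in decorated]


def divide(ranked: Sequence[str], k: int, mode: str, factor: str = "") -> GroupDivision:
    """Divide a ranked patient list into k groups.

    ordered  — k contiguous blocks; the first ``n mod k`` blocks get one
               extra patient, so sizes differ by at most one.
    balanced — rank r goes to group ``r mod k`` (stride assignment).
    """
    n = len(ranked)
    if n < k:
        raise ValueError(f"cannot divide {n} patients into {k} groups")
    if mode not in ("ordered", "balanced"):
        raise ValueError(f"mode must be 'ordered' or 'balanced', got {mode!r}")
    assignment: dict[str, int] = {}
    if mode == "balanced":
        for r, pid in enumerate(ranked):
            assignment[pid] = r % k
    else:
        base, extra = divmod(n, k)
        start = 0
        for g in range(k):
            size = base + (1 if g < extra else 0)
            for pid in ranked[start : start + size]:
                assignment[pid] = g
            start += size
    return GroupDivision(factor=factor, mode=mode, k=k, assignment=assignment)


def enumerate_allotments(k: int) -> list[RoleAllotment]:
    """All k*(k-1) (test, validation) ordered pairs, test-major order.

    Needs k >= 3 so at least one training group remains.
    """
    if k < 3:
        raise ValueError("k must be >= 3 (no training group would remain)")
    out = []
    for test in range(k):
        for val in range(k):
            if val == test:
                continue
            training = tuple(g for g in range(k) if g not in (test, val))
            out.append(RoleAllotment(test, val, training))
    return out


def check_leakage(
    division: GroupDivision,
    allotment: RoleAllotment,
    batches: Mapping[str, Iterable],
) -> LeakageReport:
    """Audit image batches for patient-level leakage.

    ``batches`` maps a role name ("training" / "validation" / "test") to an
    iterable of items carrying a ``patient_id`` attribute (images or plan
    items).  The audit fails iff any patient contributed images to more
    than one role; the report lists the offending patients.
    """
    seen: dict[str, set[str]] = {}
    for role, items in batches.items():
        for item in items:
            pid = item.patient_id if hasattr(item, "patient_id") else str(item)
            seen.setdefault(pid, set()).add(role)
    offending = {pid: sorted(roles) for pid, roles in seen.items() if len(roles) > 1}
    return LeakageReport(passed=not offending, offending=offending)


def write_division(division: GroupDivision, path: str | Path) -> None:
    """Persist a division as CSV: patient_id,factor,mode,group."""
    df = pd.DataFrame(
        {
            "patient_id": sorted(division.assignment),
            "factor": division.factor,
            "mode": division.mode,
            "group": [division.assignment[p] for p in sorted(division.assignment)],
        }
    )
    df.to_csv(path, index=False)


def read_division(path: str | Path) -> GroupDivision:
    df = pd.read_csv(path)
    required = {"patient_id", "factor", "mode", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"division file missing columns: {sorted(missing)}")
    assignment = dict(zip(df["patient_id"], df["group"].astype(int)))
    return GroupDivision(
        factor=str(df["factor"].iloc[0]),
        mode=str(df["mode"].iloc[0]),
        k=int(df["group"].max()) + 1,
        assignment=assignment,
    )
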