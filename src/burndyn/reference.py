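"""Clinical reference classification from healing time.

Burn classes are ordered by severity: 2a (superficial) < 2b1 (superficial
dermal) < 2b2 (deep dermal) < 3 (full thickness). The reference rule maps
the observed time to spontaneous wound closure to a class — closure by day
14 is 2a, closure between day 15 and 21 is 2b1, later closure or surgical
treatment is 2b2 — and the class is then assigned retrospectively to the
wound's observations on days 0-3. Full-thickness (class 3) wounds cannot
arise from the healing-time rule (they are always treated surgically) and
enter only through an explicit clinical grade-3 annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

__all__ = [
    "BurnClass",
    "HealingRecord",
    "IncompleteRecordError",
    "LabelConsistencyError",
    "classify_healing",
    "assign_retrospective",
    "read_healing_csv",
]


class BurnClass(str, Enum):
    """The four burn classes, ordered by increasing depth of damage."""

    C2A = "2a"
    C2B1 = "2b1"
    C2B2 = "2b2"
    C3 = "3"

    @property
    def severity(self) -> int:
        return ("2a", "2b1", "2b2", "3").index(self.value)

    def __lt__(self, other: "BurnClass") -> bool:  # type: ignore[override]
        return self.severity < other.severity


CLASS_ORDER = (BurnClass.C2A, BurnClass.C2B1, BurnClass.C2B2, BurnClass.C3)


class IncompleteRecordError(ValueError):
    """Healing record carries neither a closure day nor a surgical flag."""


class LabelConsistencyError(ValueError):
    """A segment carries conflicting class labels across observations."""


@dataclass(frozen=True)
class HealingRecord:
    """Healing outcome of one wound segment."""

    segment_id: str
    closure_day: int | None = None
    surgical: bool = False
    clinical_grade3: bool = False

    def __post_init__(self) -> None:
        if self.closure_day is not None and self.closure_day < 0:
            raise ValueError("closure_day must be >= 0")


def classify_healing(
    record: HealingRecord,
    day_2a: int = 14,
    day_2b1: int = 21,
) -> BurnClass:
    """Burn class from a healing record.

    Grade-3 annotation forces class 3; surgical treatment forces 2b2;
    otherwise closure by ``day_2a`` (inclusive) is 2a, closure by
    ``day_2b1`` (inclusive) is 2b1, and later closure is 2b2.
    """
    if record.clinical_grade3:
        return BurnClass.C3
    if record.surgical:
        return BurnClass.C2B2
    if record.closure_day is None:
        raise IncompleteRecordError(
            f"segment {record.segment_id}: no closure day and not surgical"
        )
    if record.closure_day <= day_2a:
        return BurnClass.C2A
    if record.closure_day <= day_2b1:
        return BurnClass.C2B1
    return BurnClass.C2B2


def assign_retrospective(
    observations: pd.DataFrame,
    class_by_segment: dict[str, BurnClass],
) -> pd.DataFrame:
    """Attach the (day-3/4) reference class to every per-day observation.

    ``observations`` needs columns ``segment_id`` and ``day``; the returned
    copy carries a ``ref_class`` column that is constant across days for a
    given segment. A segment observed with two different labels in
    ``observations`` (pre-existing ``ref_class`` column) is rejected.
    """
    if "ref_class" in observations.columns:
        for sid, grp in observations.groupby("segment_id"):
            labels = set(grp["ref_class"].dropna())
            if len(labels) > 1:
                raise LabelConsistencyError(
                    f"segment {sid} carries conflicting labels {sorted(labels)}"
                )
    out = observations.copy()
    missing = set(out["segment_id"]) - set(class_by_segment)
    if missing:
        raise KeyError(f"no reference class for segments {sorted(missing)}")
    out["ref_class"] = [
        class_by_segment[sid].value for sid in out["segment_id"]
    ]
    return out


def read_healing_csv(path) -> list[HealingRecord]:
    """Read a healing table `segment_id,closure_day,surgical,clinical_grade3`."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        day = getattr(row, "closure_day", None)
        day = None if day is None or pd.isna(day) else int(day)
        records.append(
            HealingRecord(
                segment_id=str(row.segment_id),
                closure_day=day,
                surgical=bool(getattr(row, "surgical", False)),
                clinical_grade3=bool(getattr(row, "clinical_grade3", False)),
            )
        )
    return records
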