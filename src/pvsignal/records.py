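"""Typed records mirroring the six FAERS quarterly tables.

One :class:`ReportCase` (DEMO) owns child records keyed by ``primary_id``:
drugs (DRUG), reactions (REAC), indications (INDI), therapy episodes (THER)
and outcomes (OUTC).  A :class:`Database` is the in-memory form of one
quarter-style extract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .dates import ABSENT_DATE, PartialDate

ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")
SEX_CODES = ("F", "M", "UNK")
REPORTER_CODES = (
    "physician",
    "pharmacist",
    "other health professional",
    "consumer",
    "unknown",
)
REGIONS = ("Europe", "Americas", "Asia", "Oceania", "Africa", "Unknown")

#: days per month used everywhere a duration is normalized (365.25 / 12)
DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25


@dataclass
class ReportCase:
    """One safety report version (a DEMO row)."""

    primary_id: int
    case_id: int
    case_version: int = 1
    receipt_date: PartialDate = ABSENT_DATE
    event_date: PartialDate = ABSENT_DATE
    age_value: Optional[float] = None
    age_unit: str = ""  # YR / MON / DY / '' when absent
    sex: str = "UNK"
    reporter: str = "unknown"
    country: str = ""
    region: str = "Unknown"

    def __post_init__(self) -> None:
        if self.case_version < 1:
            raise ValueError(f"case_version must be >= 1, got {self.case_version}")
        if self.sex not in SEX_CODES:
            raise ValueError(f"sex must be one of {SEX_CODES}, got {self.sex!r}")
        if self.reporter not in REPORTER_CODES:
            raise ValueError(f"unknown reporter code {self.reporter!r}")

    @property
    def age_years(self) -> Optional[float]:
        """Age normalized to years (1 month = 1/12 yr, 1 day = 1/365.25 yr)."""
        if self.age_value is None:
            return None
        unit = self.age_unit.upper()
        if unit in ("", "YR", "YEAR", "YEARS"):
            years = float(self.age_value)
        elif unit in ("MON", "MONTH", "MONTHS"):
            years = float(self.age_value) / 12.0
        elif unit in ("DY", "DAY", "DAYS"):
            years = float(self.age_value) / DAYS_PER_YEAR
        elif unit in ("DEC",):  # FAERS decade code
            years = float(self.age_value) * 10.0
        elif unit in ("WK", "WEEK", "WEEKS"):
            years = float(self.age_value) * 7.0 / DAYS_PER_YEAR
        elif unit in ("HR", "HOUR", "HOURS"):
            years = float(self.age_value) / 24.0 / DAYS_PER_YEAR
        else:
            return None
        return max(years, 0.0)


@dataclass
class DrugEntry:
    primary_id: int
    drug_seq: int
    verbatim_name: str
    role_code: str
    canonical_name: Optional[str] = None  # filled in by cleaning

    def __post_init__(self) -> None:
        if self.role_code not in ROLE_CODES:
            raise ValueError(f"role_code must be one of {ROLE_CODES}, got {self.role_code!r}")


@dataclass
class ReactionEntry:
    primary_id: int
    preferred_term: str
    soc: Optional[str] = None  # filled in by cleaning

    def __post_init__(self) -> None:
        self.preferred_term = " ".join(self.preferred_term.split())
        if not self.preferred_term:
            raise ValueError("preferred_term must be non-empty")


@dataclass
class IndicationEntry:
    primary_id: int
    drug_seq: int
    indication_text: str
    category: Optional[str] = None  # filled in by cleaning


@dataclass
class TherapyEntry:
    primary_id: int
    drug_seq: int
    start_date: PartialDate = ABSENT_DATE
    end_date: PartialDate = ABSENT_DATE
    duration_value: Optional[float] = None
    duration_unit: str = ""  # YR / MON / WK / DY / HR

    def duration_days(self) -> Optional[float]:
        """Explicit therapy duration normalized to days, if stated."""
        if self.duration_value is None:
            return None
        unit = self.duration_unit.upper()
        factor = {
            "": 1.0,
            "DY": 1.0,
            "DAY": 1.0,
            "WK": 7.0,
            "MON": DAYS_PER_MONTH,
            "YR": DAYS_PER_YEAR,
            "HR": 1.0 / 24.0,
        }.get(unit)
        if factor is None:
            return None
        return float(self.duration_value) * factor


@dataclass
class OutcomeEntry:
    primary_id: int
    outcome_code: str

    def __post_init__(self) -> None:
        if self.outcome_code not in OUTCOME_CODES:
            raise ValueError(
                f"outcome_code must be one of {OUTCOME_CODES}, got {self.outcome_code!r}"
            )


@dataclass
class Database:
    """All records of one FAERS-style extract, pre- or post-deduplication."""

    cases: List[ReportCase] = field(default_factory=list)
    drugs: List[DrugEntry] = field(default_factory=list)
    reactions: List[ReactionEntry] = field(default_factory=list)
    indications: List[IndicationEntry] = field(default_factory=list)
    therapies: List[TherapyEntry] = field(default_factory=list)
    outcomes: List[OutcomeEntry] = field(default_factory=list)

    def validate(self) -> None:
        """Check referential integrity and key uniqueness; raise ValueError."""
        pids = [c.primary_id for c in self.cases]
        if len(pids) != len(set(pids)):
            raise ValueError("primary_id values are not unique")
        pid_set = set(pids)
        drug_keys = {(d.primary_id, d.drug_seq) for d in self.drugs}
        for d in self.drugs:
            if d.primary_id not in pid_set:
                raise ValueError(f"DrugEntry references unknown primary_id {d.primary_id}")
        for i in self.indications:
            if (i.primary_id, i.drug_seq) not in drug_keys:
                raise ValueError(
                    f"IndicationEntry ({i.primary_id}, {i.drug_seq}) has no matching DrugEntry"
                )
        for t in self.therapies:
            if t.start_date.is_complete and t.end_date.is_complete:
                if t.end_date.to_date() < t.start_date.to_date():
                    raise ValueError(
                        f"TherapyEntry ({t.primary_id}, {t.drug_seq}) ends before it starts"
                    )

    def n_cases(self) -> int:
        return len(self.cases)

    def children_of(self, primary_id: int) -> Dict[str, list]:
        """All child records of one report, grouped by table."""
        return {
            "drugs": [d for d in self.drugs if d.primary_id == primary_id],
            "reactions": [r for r in self.reactions if r.primary_id == primary_id],
            "indications": [i for i in self.indications if i.primary_id == primary_id],
            "therapies": [t for t in self.therapies if t.primary_id == primary_id],
            "outcomes": [o for o in self.outcomes if o.primary_id == primary_id],
        }
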